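"""End-to-end orchestration: discovery (trio cascade) and replication
(cohort statistics), with config, logging and reports.

The two phases mirror the study design: a family trio is mined for dominant
candidate variants (``run_discovery``), and the candidates are then genotyped
in independent case/control cohorts whose count tables feed the association
statistics (``run_replication``).  Both phases are deterministic given their
inputs and seed; each run logs the package version, a config hash and the
seeds used.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .assoc_stats import (
    GenotypeCountTable,
    armitage_trend,
    fisher_exact_2x3,
    fisher_exact_allele_2x2,
    hwe_chisq,
)
from .filter_cascade import CascadeConfig, STAGE_NAMES, run_cascade
from .variant_model import (
    InputError,
    read_annotations,
    read_gene_network,
    read_pedigree,
    read_trio_vcf,
    write_trio_vcf,
)

__all__ = ["RunConfig", "run_discovery", "run_replication", "KNOWN_TESTS"]

KNOWN_TESTS = ("hwe", "fisher2x3", "allele", "armitage")

ALPHA = 0.05  # significance flag threshold; flags follow the 2x3 Fisher p only


@dataclass
class RunConfig:
    """Paths and settings for one pipeline run (loadable from YAML)."""

    vcf: Optional[str] = None
    pedigree: Optional[str] = None
    annotations: Optional[str] = None
    network: Optional[str] = None
    disease_genes: Optional[str] = None
    counts: Optional[str] = None
    out_dir: str = "trioprio_out"
    quality_key: str = "GQ"
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    tests: tuple[str, ...] = KNOWN_TESTS
    mc_reps: int = 100_000
    seed: int = 1

    def __post_init__(self) -> None:
        unknown = [t for t in self.tests if t not in KNOWN_TESTS]
        if unknown:
            raise InputError(f"unknown test name(s): {', '.join(unknown)}; "
                             f"known: {', '.join(KNOWN_TESTS)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cascade = CascadeConfig(**raw.pop("cascade", {}))
        tests = tuple(raw.pop("tests", KNOWN_TESTS))
        try:
            return cls(cascade=cascade, tests=tests, **raw)
        except TypeError as exc:
            raise InputError(f"{path}: {exc}") from exc

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise InputError("config missing required path(s): " + ", ".join(missing))
        for n in names:
            p = Path(getattr(self, n))
            if not p.exists():
                raise InputError(f"{n} path does not exist: {p}")

    def config_hash(self) -> str:
        payload = {k: (asdict(v) if isinstance(v, CascadeConfig) else v)
                   for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                              .encode()).hexdigest()[:12]


def _write_run_log(config: RunConfig, outdir: Path, phase: str) -> None:
    log = {"tool": "trioprio", "version": __version__, "phase": phase,
           "config_hash": config.config_hash(), "seed": config.seed}
    (outdir / f"{phase}_run.json").write_text(json.dumps(log, indent=2) + "\n")


def run_discovery(config: RunConfig) -> dict:
    """Run the five-stage cascade on the trio inputs; write report files.

    Outputs under ``out_dir``: kept.vcf (surviving variants), trace.tsv
    (variant key, stage, kept flag, reason), summary.json (per-stage counts
    satisfying conservation), discovery_run.json (version/seed/config hash).
    Returns the summary dict.
    """
    config.require("vcf", "pedigree", "annotations", "network", "disease_genes")
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    pedigree = read_pedigree(config.pedigree)
    config.cascade.validate_pedigree(pedigree)
    variants = read_trio_vcf(config.vcf, pedigree, quality_key=config.quality_key)
    annotations = read_annotations(config.annotations)
    network = read_gene_network(config.network, config.disease_genes,
                                warn=lambda m: warnings.warn(m))
    kept, trace = run_cascade(variants, annotations, pedigree, network, config.cascade)

    write_trio_vcf(kept, pedigree, outdir / "kept.vcf", quality_key=config.quality_key)
    rows = []
    for key, log in sorted(trace.entries.items()):
        for stage, kept_flag, reason in log:
            rows.append({"chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
                         "stage": stage, "kept": int(kept_flag), "reason": reason})
    pd.DataFrame(rows).to_csv(outdir / "trace.tsv", sep="\t", index=False)

    counts = trace.stage_counts()
    n_input = len(trace.entries)
    summary = {
        "n_input": n_input,
        "n_kept": sum(1 for k in trace.entries if trace.survived(k)),
        "stages": [{"stage": s, **counts.get(s, {"entered": 0, "kept": 0, "removed": 0})}
                   for s in STAGE_NAMES],
    }
    assert summary["n_kept"] + sum(s["removed"] for s in summary["stages"]) == n_input
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    _write_run_log(config, outdir, "discovery")
    return summary


COUNTS_COLUMNS = ["variant", "population", "arm", "n_hom_ref", "n_het", "n_hom_alt"]


def _load_count_tables(path: str | Path):
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns: {', '.join(missing)}")
    if not df["arm"].isin(["case", "control"]).all():
        raise InputError(f"{path}: arm column must be case|control")
    tables = {}
    for (variant, population), grp in df.groupby(["variant", "population"], sort=True):
        arms = {}
        for arm in ("case", "control"):
            sub = grp[grp["arm"] == arm]
            if len(sub) > 1:
                raise InputError(f"{path}: duplicate {arm} row for {variant}/{population}")
            if len(sub) == 1:
                r = sub.iloc[0]
                arms[arm] = (int(r["n_hom_ref"]), int(r["n_het"]), int(r["n_hom_alt"]))
        tables[(variant, population)] = arms
    return tables


def run_replication(config: RunConfig) -> pd.DataFrame:
    """Compute replication statistics per (variant, population) count table.

    For each table with both arms present: per-arm genotype frequencies and
    HWE p, the exact 2x3 genotype Fisher p, the allele-level 2x2 Fisher p,
    and the trend test in asymptotic and Monte-Carlo modes.  Rows are flagged
    significant iff the 2x3 Fisher p < 0.05 — no adjustment.  Arms with zero
    samples are skipped with a warning; control-only tables get HWE only.
    Writes ``replication.tsv`` under ``out_dir`` and returns the DataFrame.
    """
    config.require("counts")
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = _load_count_tables(config.counts)
    rows = []
    for (variant, population), arms in sorted(tables.items()):
        arms = {a: c for a, c in arms.items() if sum(c) > 0}
        skipped = [a for a in ("case", "control") if a not in arms]
        for a in skipped:
            warnings.warn(f"{variant}/{population}: {a} arm empty or absent; "
                          "association tests skipped")
        row: dict = {"variant": variant, "population": population}
        for arm, counts in arms.items():
            total = sum(counts)
            freqs = tuple(round(100.0 * c / total, 1) for c in counts)
            hwe = hwe_chisq(counts)
            row[f"{arm}_n"] = total
            row[f"{arm}_freq_pct"] = "/".join(f"{f:g}" for f in freqs)
            row[f"{arm}_hwe_p"] = hwe.p_value
        if len(arms) == 2:
            table = GenotypeCountTable(cases=arms["case"], controls=arms["control"])
            if "fisher2x3" in config.tests:
                row["fisher_2x3_p"] = fisher_exact_2x3(table).p_value
            if "allele" in config.tests:
                row["fisher_allele_p"] = fisher_exact_allele_2x2(table).p_value
            if "armitage" in config.tests:
                row["armitage_asymptotic_p"] = armitage_trend(table).p_value
                mc = armitage_trend(table, mode="monte_carlo", reps=config.mc_reps,
                                    seed=config.seed)
                row["armitage_mc_p"] = mc.p_value
            if "fisher2x3" in config.tests:
                row["significant"] = bool(row["fisher_2x3_p"] < ALPHA)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "replication.tsv", sep="\t", index=False)
    _write_run_log(config, outdir, "replication")
    return df
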