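"""Synthetic trio and cohort generators emulating a family-genomics study.

No genomes are deposited with family studies of this kind, so the package
ships a generator that reproduces the *structure* the analysis assumes:

* ``simulate_trio`` — a father/mother/daughter trio (father unaffected,
  mother and daughter affected) with one planted, highly penetrant causal
  variant transmitted mother->daughter as a heterozygote, embedded among
  background variants whose population allele frequencies, per-sample
  genotypes (Hardy-Weinberg parents, Mendelian child) and Phred call
  qualities are drawn from configurable models.  Annotations are generated so
  the planted variant satisfies the frequency, deleteriousness and biological
  context filters by construction, while background variants fail each filter
  at realistic rates.
* ``simulate_cohort_table`` — case/control genotype counts at a biallelic
  locus: controls multinomial under Hardy-Weinberg at allele frequency p;
  cases under a multiplicative genotype-relative-risk model (het risk x gamma,
  hom-alt x gamma^2), the standard single-locus generative model for
  case-control data.  Defaults mirror a cohort of 109 cases / 111 controls.

One global integer seed drives a named stream per component, so e.g. adding
background variants never perturbs the cohort draws.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .assoc_stats import GenotypeCountTable
from .variant_model import (
    AnnotationBundle,
    GeneNetwork,
    GenotypeCall,
    Pedigree,
    PedigreeMember,
    VariantKey,
    VariantRecord,
    write_annotations,
    write_pedigree,
    write_trio_vcf,
)

__all__ = [
    "TrioSimSpec",
    "CohortSimSpec",
    "PlantedVariantSpec",
    "QualityModel",
    "TrioSimulation",
    "simulate_trio",
    "simulate_cohort_table",
    "trio_pedigree",
    "write_trio_bundle",
]

_BASES = np.array(list("ACGT"))


def _stream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of one global seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class QualityModel:
    """Phred call-quality model: Normal(mean, sd) clipped at 0, with a
    ``low_quality_fraction`` of calls redrawn uniformly below 20."""

    mean: float = 45.0
    sd: float = 8.0
    low_quality_fraction: float = 0.05

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        q = np.clip(rng.normal(self.mean, self.sd, size=size), 0.0, None)
        low = rng.random(size=size) < self.low_quality_fraction
        q[low] = rng.uniform(0.0, 20.0, size=int(low.sum()))
        return np.round(q, 1)


@dataclass(frozen=True)
class PlantedVariantSpec:
    """The causal variant planted in the trio: heterozygous in the affected
    mother and daughter, absent from the unaffected father (at full
    penetrance), rare in every reference panel, protein-damaging, and in a
    disease-context gene — so it survives every cascade stage by
    construction."""

    gene: str = "NCK2"
    chrom: str = "2"
    pos: int = 106_000_000
    ref: str = "AA"
    alt: str = "G"
    consequence: str = "frameshift"
    sift_score: Optional[float] = None
    provean_score: float = -1.97
    af_1kg: Optional[float] = None
    af_cg69: Optional[float] = None
    af_esp: Optional[float] = None
    quality: float = 55.0


@dataclass(frozen=True)
class TrioSimSpec:
    """Conditions for one simulated trio dataset.

    ``af_spectrum`` gives (a, b, lo, hi): background population allele
    frequencies are Beta(a, b) truncated to (lo, hi), so both common (>= 3 %)
    and rare variants occur and the frequency filter is exercised in both
    directions.  ``penetrance`` is the probability an unaffected carrier is
    impossible; below 1.0 the unaffected father may carry the planted allele
    with probability 1 - penetrance.
    """

    n_background: int = 2000
    af_spectrum: tuple[float, float, float, float] = (0.3, 3.0, 0.0005, 0.5)
    quality_model: QualityModel = field(default_factory=QualityModel)
    planted: PlantedVariantSpec = field(default_factory=PlantedVariantSpec)
    penetrance: float = 1.0
    n_genes: int = 200
    disease_gene_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        if not (0.0 < self.penetrance <= 1.0):
            raise ValueError("penetrance must be in (0, 1]")
        for af in (self.planted.af_1kg, self.planted.af_cg69, self.planted.af_esp):
            if af is not None and af >= 0.03:
                raise ValueError(
                    "contradictory spec: planted variant has panel allele frequency "
                    f">= 3 % ({af}) and could not survive the frequency filter")


@dataclass(frozen=True)
class CohortSimSpec:
    """Conditions for one simulated case/control cohort at a single locus."""

    allele_freq: float = 0.1
    n_cases: int = 109
    n_controls: int = 111
    grr: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.allele_freq < 1.0):
            raise ValueError("allele_freq must lie in (0, 1)")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("cohort arms must be non-empty")
        if self.grr <= 0:
            raise ValueError("genotype relative risk must be positive")

    def control_probs(self) -> np.ndarray:
        p = self.allele_freq
        return np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])

    def case_probs(self) -> np.ndarray:
        w = self.control_probs() * np.array([1.0, self.grr, self.grr ** 2])
        return w / w.sum()


@dataclass
class TrioSimulation:
    """Output of :func:`simulate_trio`."""

    variants: list[VariantRecord]
    annotations: dict[VariantKey, AnnotationBundle]
    truth: dict
    pedigree: Pedigree
    network: GeneNetwork


def trio_pedigree() -> Pedigree:
    """The study pedigree: unaffected father, affected mother and daughter."""
    return Pedigree((
        PedigreeMember("III-1", "control", "father"),
        PedigreeMember("III-2", "case", "mother"),
        PedigreeMember("IV-3", "case", "daughter", father="III-1", mother="III-2"),
    ))


def _truncated_beta(rng: np.random.Generator, a: float, b: float,
                    lo: float, hi: float, size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.beta(a, b, size=max(size - filled, 16))
        ok = draw[(draw > lo) & (draw < hi)]
        take = min(len(ok), size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


_CONSEQUENCE_CHOICES = np.array([
    "synonymous", "other", "missense", "splice_region", "frameshift",
    "inframe_indel", "stop_change", "structural",
])
_CONSEQUENCE_PROBS = np.array([0.40, 0.25, 0.20, 0.05, 0.04, 0.03, 0.02, 0.01])


def _background_annotation(rng: np.random.Generator, gene: str,
                           pop_af: float) -> AnnotationBundle:
    """Panel frequencies scatter around the population frequency; consequences
    and predictor scores follow field-realistic proportions."""
    def panel_af() -> Optional[float]:
        if rng.random() < 0.15:
            return None
        return float(np.clip(pop_af * rng.lognormal(0.0, 0.25), 0.0, 1.0))

    consequence = str(rng.choice(_CONSEQUENCE_CHOICES, p=_CONSEQUENCE_PROBS))
    sift = float(np.round(rng.random(), 3)) if consequence == "missense" and rng.random() > 0.2 else None
    offset = int(rng.integers(1, 12)) if consequence == "splice_region" else None
    assertion = "unknown_significance" if rng.random() < 0.01 else "none"
    return AnnotationBundle(
        gene=gene,
        af_1kg=panel_af(), af_cg69=panel_af(), af_esp=panel_af(),
        clinical_assertion=assertion,
        gof_literature=bool(rng.random() < 0.002),
        inferred_activating=bool(rng.random() < 0.002),
        bsift_gof=bool(rng.random() < 0.002),
        mirna_site=bool(rng.random() < 0.005),
        consequence=consequence,
        splice_intron_offset=offset,
        sift_score=sift,
        provean_score=float(np.round(rng.normal(-1.0, 1.5), 2)),
    )


def _make_network(rng: np.random.Generator, genes: list[str], planted_gene: str,
                  disease_fraction: float) -> GeneNetwork:
    n_disease = max(3, int(round(disease_fraction * len(genes))))
    disease = set(rng.choice(genes, size=n_disease, replace=False).tolist())
    disease.add(planted_gene)
    edges = set()
    for g in genes:
        for _ in range(int(rng.integers(1, 3))):
            target = str(rng.choice(genes))
            if target != g:
                edges.add((g, target))
    return GeneNetwork(edges=frozenset(edges), disease_genes=frozenset(disease))


def simulate_trio(spec: TrioSimSpec) -> TrioSimulation:
    """Simulate a trio dataset with a planted dominant causal variant.

    Background variants: population allele frequency from the truncated Beta
    spectrum; the four parental alleles are Bernoulli(af) draws
    (Hardy-Weinberg) conditioned on at least one alternate allele, since a
    multi-sample VCF only lists sites present in some sample; the child
    receives one uniformly chosen allele from each parent, so every child
    genotype is Mendelian-consistent.  Call qualities
    come from the quality model.  The planted variant is heterozygous in both
    cases with quality above the confidence threshold and hom-ref in the
    control (at penetrance 1).  Identical spec+seed gives identical output.
    """
    rng = _stream(spec.seed, "trio")
    ped = trio_pedigree()
    genes = [f"GENE{i:04d}" for i in range(spec.n_genes)]
    network = _make_network(_stream(spec.seed, "network"), genes,
                            spec.planted.gene, spec.disease_gene_fraction)

    n = spec.n_background
    a, b, lo, hi = spec.af_spectrum
    afs = _truncated_beta(rng, a, b, lo, hi, n)
    chroms = rng.integers(1, 23, size=n)
    positions = rng.integers(10_000, 200_000_000, size=n)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4

    # Parental alleles: 4 Bernoulli(af) draws conditioned on >= 1 alternate
    # allele (a multi-sample VCF only lists sites someone carries), sampled
    # exactly: K ~ Binomial(4, af) | K >= 1, placed uniformly at random.
    if n > 0:
        k_range = np.arange(1, 5)
        binom_coef = np.array([4.0, 6.0, 4.0, 1.0])
        pk = (binom_coef[None, :] * afs[:, None] ** k_range[None, :]
              * (1 - afs[:, None]) ** (4 - k_range[None, :]))
        pk /= pk.sum(axis=1, keepdims=True)
        u = rng.random(n)
        k = 1 + (u[:, None] > np.cumsum(pk, axis=1)).sum(axis=1)
        order = np.argsort(rng.random((n, 4)), axis=1)
        alleles = (np.argsort(order, axis=1) < k[:, None])
    else:
        alleles = np.zeros((0, 4), dtype=bool)
    father, mother = alleles[:, :2], alleles[:, 2:]
    pick = rng.integers(0, 2, size=(n, 2))
    child = np.stack([father[np.arange(n), pick[:, 0]],
                      mother[np.arange(n), pick[:, 1]]], axis=1)
    quality = spec.quality_model.draw(rng, (n, 3))

    variants: list[VariantRecord] = []
    annotations: dict[VariantKey, AnnotationBundle] = {}
    seen_keys: set[VariantKey] = set()
    ann_rng = _stream(spec.seed, "annotations")
    for i in range(n):
        key = (str(chroms[i]), int(positions[i]), str(_BASES[ref_idx[i]]),
               str(_BASES[alt_idx[i]]))
        if key in seen_keys:  # vanishingly rare collision; skip
            continue
        seen_keys.add(key)
        gene = genes[int(ann_rng.integers(0, len(genes)))]
        calls = {
            "III-1": GenotypeCall(tuple(sorted(int(x) for x in father[i])), float(quality[i, 0])),
            "III-2": GenotypeCall(tuple(sorted(int(x) for x in mother[i])), float(quality[i, 1])),
            "IV-3": GenotypeCall(tuple(sorted(int(x) for x in child[i])), float(quality[i, 2])),
        }
        variants.append(VariantRecord(chrom=key[0], pos=key[1], ref=key[2],
                                      alts=(key[3],), gene=gene, calls=calls))
        annotations[key] = _background_annotation(ann_rng, gene, float(afs[i]))

    pv = spec.planted
    father_carries = spec.penetrance < 1.0 and rng.random() < (1.0 - spec.penetrance)
    planted_calls = {
        "III-1": GenotypeCall((0, 1) if father_carries else (0, 0), pv.quality),
        "III-2": GenotypeCall((0, 1), pv.quality),
        "IV-3": GenotypeCall((0, 1), pv.quality),
    }
    planted = VariantRecord(chrom=pv.chrom, pos=pv.pos, ref=pv.ref,
                            alts=(pv.alt,), gene=pv.gene, calls=planted_calls)
    planted_key = planted.key()
    variants.append(planted)
    annotations[planted_key] = AnnotationBundle(
        gene=pv.gene, af_1kg=pv.af_1kg, af_cg69=pv.af_cg69, af_esp=pv.af_esp,
        consequence=pv.consequence, sift_score=pv.sift_score,
        provean_score=pv.provean_score,
    )
    variants.sort(key=lambda v: (int(v.chrom), v.pos, v.ref, v.alts))
    truth = {
        "planted": {"chrom": planted_key[0], "pos": planted_key[1],
                    "ref": planted_key[2], "alt": planted_key[3],
                    "gene": pv.gene},
        "father_carries": bool(father_carries),
        "seed": spec.seed,
        "n_background": n,
    }
    return TrioSimulation(variants=variants, annotations=annotations,
                          truth=truth, pedigree=ped, network=network)


def simulate_cohort_table(spec: CohortSimSpec) -> GenotypeCountTable:
    """Draw a 2x3 case/control genotype count table under the GRR model.

    Controls are multinomial with Hardy-Weinberg probabilities at allele
    frequency p; case probabilities are the HWE probabilities reweighted by
    (1, gamma, gamma^2) and renormalized.  At gamma = 1 the two arms are
    exchangeable.
    """
    rng = _stream(spec.seed, "cohort")
    cases = rng.multinomial(spec.n_cases, spec.case_probs())
    controls = rng.multinomial(spec.n_controls, spec.control_probs())
    return GenotypeCountTable(cases=tuple(int(c) for c in cases),
                              controls=tuple(int(c) for c in controls))


def write_trio_bundle(sim: TrioSimulation, outdir: str | Path,
                      quality_key: str = "GQ") -> dict[str, Path]:
    """Write a simulated trio as the file dialects the readers consume.

    Emits trio.vcf, trio.ped, annotations.tsv, network.tsv, disease_genes.txt
    and truth.json; returns the paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "trio.vcf",
        "pedigree": outdir / "trio.ped",
        "annotations": outdir / "annotations.tsv",
        "network": outdir / "network.tsv",
        "disease_genes": outdir / "disease_genes.txt",
        "truth": outdir / "truth.json",
    }
    write_trio_vcf(sim.variants, sim.pedigree, paths["vcf"], quality_key=quality_key)
    write_pedigree(sim.pedigree, paths["pedigree"])
    write_annotations(sim.annotations, paths["annotations"])
    edge_lines = sorted(f"{a}\t{b}" for a, b in sim.network.edges)
    paths["network"].write_text("\n".join(edge_lines) + "\n")
    paths["disease_genes"].write_text("\n".join(sorted(sim.network.disease_genes)) + "\n")
    paths["truth"].write_text(json.dumps(sim.truth, indent=2, sort_keys=True) + "\n")
    return paths
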