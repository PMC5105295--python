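"""Core data types and I/O for trio genotype data.

The unit flowing through the prioritization cascade is a :class:`VariantRecord`
(one VCF data line, multi-allelic sites preserved) carrying per-sample
:class:`GenotypeCall` objects.  Auxiliary inputs are a :class:`Pedigree`
(case/control roles plus family edges), per-variant :class:`AnnotationBundle`
objects keyed by ``(chrom, pos, ref, alt)``, and a :class:`GeneNetwork`
(directed regulator->target edges plus a disease-gene set).

Coordinates are 1-based throughout, as in VCF.  Missing values stay missing
(``None``), never zero: each downstream filter states its own missing-value
rule.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "Zygosity",
    "GenotypeCall",
    "VariantRecord",
    "Pedigree",
    "AnnotationBundle",
    "GeneNetwork",
    "FilterTrace",
    "TraceEntry",
    "VariantKey",
    "InputError",
    "phred_accuracy",
    "read_trio_vcf",
    "write_trio_vcf",
    "read_pedigree",
    "write_pedigree",
    "read_annotations",
    "write_annotations",
    "read_gene_network",
]

VariantKey = tuple[str, int, str, str]

_VALID_BASES = set("ACGTN")

CLINICAL_ASSERTIONS = frozenset(
    {"pathogenic", "possibly_pathogenic", "unknown_significance", "benign", "none"}
)
CONSEQUENCES = frozenset(
    {
        "frameshift",
        "inframe_indel",
        "stop_change",
        "missense",
        "synonymous",
        "splice_region",
        "structural",
        "other",
    }
)


class InputError(ValueError):
    """Raised for malformed or inconsistent input files (exit code 1 in the CLI)."""


def phred_accuracy(quality: float) -> float:
    """Call accuracy implied by a Phred-scaled quality: ``1 - 10**(-Q/10)``.

    Q20 corresponds to 99 % accuracy, the confidence threshold of the
    cascade's first stage.
    """
    if quality < 0:
        raise ValueError("Phred quality must be >= 0")
    return 1.0 - 10.0 ** (-quality / 10.0)


class Zygosity(str, enum.Enum):
    """Genotype class derived purely from the called allele indices.

    ``heterozygous_alt`` is a het call over two distinct alternate alleles;
    ``heterozygous_amb`` is a het call where one allele is uncalled but the
    called one is an alternate; a diploid call with an uncalled allele and a
    called *reference* allele carries no carrier information and is classed
    ``missing``.  ``hemizygous`` is any single-allele call.
    """

    HOM_REF = "hom_ref"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS_ALT = "heterozygous_alt"
    HETEROZYGOUS_AMB = "heterozygous_amb"
    HEMIZYGOUS = "hemizygous"
    MISSING = "missing"


#: Genotype classes counted as carrying at least one alternate allele.
CARRIER_CLASSES = frozenset(
    {
        Zygosity.HETEROZYGOUS,
        Zygosity.HOMOZYGOUS,
        Zygosity.HETEROZYGOUS_ALT,
        Zygosity.HETEROZYGOUS_AMB,
        Zygosity.HEMIZYGOUS,
    }
)


def derive_zygosity(allele_indices: Optional[tuple[int, ...]]) -> Zygosity:
    """Map called allele indices to a :class:`Zygosity` class.

    ``allele_indices`` uses the VCF convention: 0 = reference, k = k-th
    alternate, -1 = uncalled.  ``None`` or an all-uncalled tuple is missing.
    The mapping is total: every legal GT maps to exactly one class.
    """
    if allele_indices is None:
        return Zygosity.MISSING
    alleles = tuple(allele_indices)
    if len(alleles) == 1:
        if alleles[0] < 0:
            return Zygosity.MISSING
        return Zygosity.HEMIZYGOUS
    if len(alleles) != 2:
        raise ValueError(f"only haploid/diploid calls supported, got {alleles!r}")
    a, b = alleles
    if a < 0 and b < 0:
        return Zygosity.MISSING
    if a < 0 or b < 0:
        known = a if a >= 0 else b
        return Zygosity.HETEROZYGOUS_AMB if known > 0 else Zygosity.MISSING
    if a == b:
        return Zygosity.HOM_REF if a == 0 else Zygosity.HOMOZYGOUS
    if a == 0 or b == 0:
        return Zygosity.HETEROZYGOUS
    return Zygosity.HETEROZYGOUS_ALT


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one variant: allele indices plus Phred quality."""

    allele_indices: Optional[tuple[int, ...]] = None
    quality: Optional[float] = None

    def __post_init__(self) -> None:
        if self.quality is not None and (self.quality < 0 or math.isnan(self.quality)):
            raise ValueError("Phred quality must be >= 0 or missing")

    @property
    def zygosity(self) -> Zygosity:
        return derive_zygosity(self.allele_indices)

    @property
    def is_carrier(self) -> bool:
        """True iff the call contains at least one alternate allele.

        Note a hemizygous call of the *reference* allele is not a carrier,
        although hemizygous is one of the qualifying genotype classes.
        """
        return self.allele_indices is not None and any(a > 0 for a in self.allele_indices)

    def carries_alt(self, alt_index: int) -> bool:
        """True iff the specific 1-based alternate ``alt_index`` was called."""
        if self.allele_indices is None:
            return False
        return alt_index in self.allele_indices

    def gt_string(self) -> str:
        if self.allele_indices is None:
            return "./."
        return "/".join("." if a < 0 else str(a) for a in self.allele_indices)


@dataclass
class VariantRecord:
    """One genomic variant with per-sample genotype calls and qualities."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    gene: str = ""
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        self.alts = tuple(self.alts)
        for allele in (self.ref, *self.alts):
            if not allele:
                raise ValueError("empty allele string")
            if allele.startswith("<") and allele.endswith(">"):
                continue  # symbolic structural allele
            if not set(allele.upper()) <= _VALID_BASES:
                raise ValueError(f"allele {allele!r} not over ACGTN")

    def key(self, alt_index: int = 1) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alts[alt_index - 1])

    @property
    def is_structural(self) -> bool:
        return any(a.startswith("<") for a in self.alts)

    def carrier_samples(self) -> list[str]:
        return [s for s, c in self.calls.items() if c.is_carrier]


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    role: str  # "case" | "control"
    relation: str = ""
    father: Optional[str] = None
    mother: Optional[str] = None


@dataclass
class Pedigree:
    """Sample roles and family structure; defines "cases" and "controls"."""

    members: tuple[PedigreeMember, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.members:
            if m.role not in ("case", "control"):
                raise InputError(f"role must be case|control, got {m.role!r} for {m.sample_id}")
            if m.sample_id in seen:
                raise InputError(f"duplicate sample id {m.sample_id!r}")
            seen.add(m.sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.members]

    @property
    def cases(self) -> list[str]:
        return [m.sample_id for m in self.members if m.role == "case"]

    @property
    def controls(self) -> list[str]:
        return [m.sample_id for m in self.members if m.role == "control"]

    def parent_child_edges(self) -> list[tuple[str, str]]:
        edges = []
        for m in self.members:
            for p in (m.father, m.mother):
                if p:
                    edges.append((p, m.sample_id))
        return edges


@dataclass(frozen=True)
class AnnotationBundle:
    """Per-variant annotation consumed by the cascade.

    Allele frequencies come from three reference panels (1000 Genomes, the 69
    public Complete Genomics genomes, NHLBI ESP exomes).  Scores from protein
    impact predictors (SIFT in [0,1], lower = more damaging; PROVEAN delta
    alignment score, more negative = more deleterious) are inputs, never
    computed here.  Absent values are ``None``, never 0.
    """

    gene: str = ""
    af_1kg: Optional[float] = None
    af_cg69: Optional[float] = None
    af_esp: Optional[float] = None
    clinical_assertion: str = "none"
    gof_literature: bool = False
    inferred_activating: bool = False
    bsift_gof: bool = False
    mirna_site: bool = False
    consequence: str = "other"
    splice_intron_offset: Optional[int] = None
    sift_score: Optional[float] = None
    provean_score: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("af_1kg", "af_cg69", "af_esp"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.sift_score is not None and not (0.0 <= self.sift_score <= 1.0):
            raise ValueError(f"sift_score={self.sift_score} outside [0,1]")
        if self.clinical_assertion not in CLINICAL_ASSERTIONS:
            raise ValueError(f"unknown clinical assertion {self.clinical_assertion!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def frequencies(self) -> tuple[Optional[float], Optional[float], Optional[float]]:
        return (self.af_1kg, self.af_cg69, self.af_esp)


@dataclass
class GeneNetwork:
    """Directed gene-interaction edges plus a disease-gene set.

    The biological-context rule keeps a gene iff it is a disease gene itself
    or lies within one hop of one (an edge in either direction).  Self-loops
    are allowed in the edge list but never create context on their own.
    """

    edges: frozenset[tuple[str, str]] = frozenset()
    disease_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if not a or not b:
                raise InputError("network edge with empty gene symbol")
        self.edges = frozenset(self.edges)
        self.disease_genes = frozenset(self.disease_genes)
        neighbors: dict[str, set[str]] = {}
        for a, b in self.edges:
            if a == b:
                continue
            neighbors.setdefault(a, set()).add(b)
            neighbors.setdefault(b, set()).add(a)
        self._neighbors = neighbors

    def in_disease_context(self, gene: str) -> bool:
        """True iff ``gene`` is a disease gene or a direct network neighbor of one."""
        if gene in self.disease_genes:
            return True
        return bool(self._neighbors.get(gene, set()) & self.disease_genes)


TraceEntry = tuple[str, bool, str]  # (stage name, kept flag, reason)


@dataclass
class FilterTrace:
    """Per-variant audit of the cascade: which stage kept or removed it.

    A variant removed at stage *k* has no entries past *k*; a surviving variant
    has one kept entry per stage.  ``check_conservation`` asserts that the kept
    set equals the input set minus the union of removed sets.
    """

    entries: dict[VariantKey, list[TraceEntry]] = field(default_factory=dict)

    def record(self, key: VariantKey, stage: str, kept: bool, reason: str = "") -> None:
        log = self.entries.setdefault(key, [])
        if log and not log[-1][1]:
            raise ValueError(f"variant {key} already removed at {log[-1][0]}")
        log.append((stage, kept, reason))

    def removal_stage(self, key: VariantKey) -> Optional[str]:
        log = self.entries.get(key, [])
        if log and not log[-1][1]:
            return log[-1][0]
        return None

    def survived(self, key: VariantKey, n_stages: int = 5) -> bool:
        log = self.entries.get(key, [])
        return len(log) == n_stages and all(kept for _, kept, _ in log)

    def check_conservation(self, input_keys: Iterable[VariantKey], kept_keys: Iterable[VariantKey],
                           n_stages: int = 5) -> None:
        input_set, kept_set = set(input_keys), set(kept_keys)
        removed = {k for k in self.entries if self.removal_stage(k) is not None}
        if kept_set != input_set - removed:
            raise AssertionError("trace conservation violated: kept != input - removed")
        for k in kept_set:
            if not self.survived(k, n_stages):
                raise AssertionError(f"kept variant {k} lacks a full survival trace")

    def stage_counts(self) -> dict[str, dict[str, int]]:
        """Per stage: how many variants entered, were kept, were removed."""
        counts: dict[str, dict[str, int]] = {}
        for log in self.entries.values():
            for stage, kept, _ in log:
                c = counts.setdefault(stage, {"entered": 0, "kept": 0, "removed": 0})
                c["entered"] += 1
                c["kept" if kept else "removed"] += 1
        return counts


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> Pedigree:
    """Read a whitespace-delimited pedigree: sample_id role relation [father mother].

    ``.`` (or ``0``) marks an absent parent.
    """
    members = []
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise InputError(f"{path}:{line_no}: expected >=3 columns, got {len(parts)}")
        father = parts[3] if len(parts) > 3 and parts[3] not in (".", "0") else None
        mother = parts[4] if len(parts) > 4 and parts[4] not in (".", "0") else None
        members.append(PedigreeMember(parts[0], parts[1], parts[2], father, mother))
    if not members:
        raise InputError(f"{path}: empty pedigree")
    return Pedigree(tuple(members))


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    lines = ["#sample_id\trole\trelation\tfather\tmother"]
    for m in pedigree.members:
        lines.append("\t".join([m.sample_id, m.role, m.relation or ".",
                                m.father or ".", m.mother or "."]))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_gq(value) -> Optional[float]:
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    # cyvcf2 encodes missing integers as large negative sentinels
    if math.isnan(v) or v < 0:
        return None
    return v


def read_trio_vcf(path: str | Path, pedigree: Pedigree,
                  quality_key: str = "GQ") -> list[VariantRecord]:
    """Read a VCF into :class:`VariantRecord` objects, one per data line.

    Multi-allelic sites are preserved with indexed alternate alleles.  The
    per-sample Phred call quality is read from the FORMAT field named by
    ``quality_key`` (default GQ); platforms with non-standard quality encodings
    can point this at another numeric FORMAT key.

    Raises :class:`InputError` if any pedigree member lacks a sample column.
    Malformed genotypes are collected per record and reported together.
    """
    vcf = VCF(str(path))
    sample_index = {s: i for i, s in enumerate(vcf.samples)}
    missing = [s for s in pedigree.sample_ids if s not in sample_index]
    if missing:
        raise InputError(f"{path}: VCF lacks sample column(s) for pedigree member(s): "
                         + ", ".join(missing))
    records: list[VariantRecord] = []
    problems: list[str] = []
    for v in vcf:
        try:
            gq = v.format(quality_key)
        except KeyError:
            gq = None
        calls: dict[str, GenotypeCall] = {}
        for sample in pedigree.sample_ids:
            i = sample_index[sample]
            gt = v.genotypes[i]
            alleles = tuple(int(a) for a in gt[:-1])  # last element is phasing flag
            if all(a < 0 for a in alleles):
                alleles = None
            quality = _parse_gq(gq[i][0] if gq is not None else None)
            try:
                calls[sample] = GenotypeCall(alleles, quality)
            except ValueError as exc:  # pragma: no cover - defensive
                problems.append(f"{v.CHROM}:{v.POS} sample {sample}: {exc}")
                calls[sample] = GenotypeCall(None, None)
        gene = v.INFO.get("GENE") or ""
        records.append(VariantRecord(chrom=v.CHROM, pos=v.POS, ref=v.REF,
                                     alts=tuple(v.ALT), gene=gene, calls=calls))
    if problems:
        raise InputError(f"{path}: malformed genotypes:\n" + "\n".join(problems))
    return records


def write_trio_vcf(records: Sequence[VariantRecord], pedigree: Pedigree,
                   path: str | Path, quality_key: str = "GQ") -> None:
    """Write records in the VCF v4.2 dialect :func:`read_trio_vcf` reads.

    Qualities are rounded to one decimal; round-tripping preserves every field
    the model carries.
    """
    samples = pedigree.sample_ids
    contigs = []
    for r in records:
        if r.chrom not in contigs:
            contigs.append(r.chrom)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(f'##FORMAT=<ID={quality_key},Number=1,Type=Float,'
                 'Description="Phred-scaled call quality">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
                 + "\t".join(["FORMAT"] + samples))
    for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alts)):
        info = f"GENE={r.gene}" if r.gene else "."
        cols = [r.chrom, str(r.pos), ".", r.ref, ",".join(r.alts), ".", "PASS",
                info, f"GT:{quality_key}"]
        for s in samples:
            call = r.calls.get(s, GenotypeCall())
            q = "." if call.quality is None else f"{call.quality:.1f}"
            cols.append(f"{call.gt_string()}:{q}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "af_1kg", "af_cg69", "af_esp",
    "clinical_assertion", "gof_literature", "inferred_activating", "bsift_gof",
    "mirna_site", "consequence", "splice_intron_offset", "sift_score",
    "provean_score",
]

_FLAG_COLUMNS = ("gof_literature", "inferred_activating", "bsift_gof", "mirna_site")


def read_annotations(path: str | Path) -> dict[VariantKey, AnnotationBundle]:
    """Read the tab-separated annotation table into bundles keyed by variant.

    Absent cells become missing values, never zeros.  Duplicate keys and
    frequencies outside [0,1] are fatal, reported with the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise InputError(f"{path}: missing columns: {', '.join(missing_cols)}")
    out: dict[VariantKey, AnnotationBundle] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        key: VariantKey = (d["chrom"], int(d["pos"]), d["ref"], d["alt"])
        if key in out:
            raise InputError(f"{path}: row {row_no}: duplicate variant key {key}")

        def opt_float(col: str) -> Optional[float]:
            raw = d[col].strip()
            return float(raw) if raw not in ("", ".", "NA") else None

        def opt_int(col: str) -> Optional[int]:
            raw = d[col].strip()
            return int(raw) if raw not in ("", ".", "NA") else None

        try:
            bundle = AnnotationBundle(
                gene=d["gene"].strip(),
                af_1kg=opt_float("af_1kg"),
                af_cg69=opt_float("af_cg69"),
                af_esp=opt_float("af_esp"),
                clinical_assertion=d["clinical_assertion"].strip() or "none",
                consequence=d["consequence"].strip() or "other",
                splice_intron_offset=opt_int("splice_intron_offset"),
                sift_score=opt_float("sift_score"),
                provean_score=opt_float("provean_score"),
                **{c: d[c].strip().lower() in ("1", "true", "yes") for c in _FLAG_COLUMNS},
            )
        except ValueError as exc:
            raise InputError(f"{path}: row {row_no}: {exc}") from exc
        out[key] = bundle
    return out


def write_annotations(annotations: Mapping[VariantKey, AnnotationBundle],
                      path: str | Path) -> None:
    rows = []
    for (chrom, pos, ref, alt), b in annotations.items():
        rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "gene": b.gene,
            "af_1kg": "" if b.af_1kg is None else b.af_1kg,
            "af_cg69": "" if b.af_cg69 is None else b.af_cg69,
            "af_esp": "" if b.af_esp is None else b.af_esp,
            "clinical_assertion": b.clinical_assertion,
            "gof_literature": int(b.gof_literature),
            "inferred_activating": int(b.inferred_activating),
            "bsift_gof": int(b.bsift_gof),
            "mirna_site": int(b.mirna_site),
            "consequence": b.consequence,
            "splice_intron_offset": "" if b.splice_intron_offset is None else b.splice_intron_offset,
            "sift_score": "" if b.sift_score is None else b.sift_score,
            "provean_score": "" if b.provean_score is None else b.provean_score,
        })
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_network(path: str | Path, disease_genes_path: str | Path,
                      warn=None) -> GeneNetwork:
    """Read a 2-column TSV edge list and a one-symbol-per-line disease-gene list.

    Duplicate edges are collapsed.  An empty disease set is legal but makes the
    context filter remove everything; a warning callback may be supplied.
    """
    edges: set[tuple[str, str]] = set()
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise InputError(f"{path}:{line_no}: expected 2 columns")
        edges.add((parts[0], parts[1]))
    disease = {
        line.strip() for line in Path(disease_genes_path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    if not disease and warn is not None:
        warn("empty disease-gene set: the biological-context filter will remove everything")
    return GeneNetwork(edges=frozenset(edges), disease_genes=frozenset(disease))
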