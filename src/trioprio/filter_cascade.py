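"""The five-stage trio variant-prioritization cascade.

Stages, applied in fixed order, each shrinking the candidate set:

1. **Confidence** — keep a variant iff all quality-bearing carrier calls in
   the case group, or all in the control group, reach the Phred threshold
   (default 20.0, i.e. 99 % call accuracy).  The group rule defaults to OR
   ("any_group"), switchable to AND.
2. **Common variants** — remove a variant whose allele frequency is >= 3 %
   (inclusive) in any of the three reference panels; missing frequencies
   never remove.
3. **Predicted deleterious** — keep a variant matching any of an OR-chained
   criterion list: a clinical assertion (pathogenic / possibly pathogenic /
   unknown significance), gain-of-function evidence (literature, inferred,
   predicted), a microRNA binding site, a protein-truncating or structural
   consequence (frameshift, in-frame indel, stop change, structural),
   missense not predicted innocuous by SIFT (score <= 0.05 or missing), or a
   splice-region change at most 2 bases into the intron.
4. **Genetic analysis** (autosomal-dominant segregation) — keep a variant iff
   at least ``min_case_samples`` distinct case samples carry a qualifying
   genotype at *some* surviving variant of its gene (gene-level counting, so
   compound heterozygotes qualify) AND at most ``max_control_samples``
   control samples carry the variant itself.
5. **Biological context** — keep a variant iff its gene is a disease gene or
   lies within one hop of one in the interaction network.

Every decision is recorded in a :class:`~trioprio.variant_model.FilterTrace`;
a removed variant records its first failing stage only, so conservation
(kept = input minus removed) is checkable.

Multi-allelic records are not decomposed: the cascade unit is a
(variant, alt-index) pair sharing the record's genotype calls, with the
annotation bundle looked up per alternate allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional, Sequence

from .variant_model import (
    AnnotationBundle,
    FilterTrace,
    GeneNetwork,
    Pedigree,
    VariantKey,
    VariantRecord,
)

__all__ = [
    "CascadeConfig",
    "CascadeItem",
    "STAGE_NAMES",
    "expand_items",
    "confidence_filter",
    "common_variant_filter",
    "deleteriousness_filter",
    "genetic_model_filter",
    "biological_context_filter",
    "run_cascade",
]

STAGE_NAMES = (
    "confidence",
    "common_variants",
    "predicted_deleterious",
    "genetic_analysis",
    "biological_context",
)

KEEP_ASSERTIONS = frozenset({"pathogenic", "possibly_pathogenic", "unknown_significance"})
TRUNCATING_CONSEQUENCES = frozenset({"frameshift", "inframe_indel", "stop_change", "structural"})


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds of the cascade; defaults are the published ones."""

    quality_threshold: float = 20.0
    af_cutoff: float = 0.03
    splice_max_offset: int = 2
    min_case_samples: int = 2
    max_control_samples: int = 0
    quality_group_rule: str = "any_group"  # or "all_groups"

    def __post_init__(self) -> None:
        if self.quality_threshold < 0 or self.af_cutoff < 0:
            raise ValueError("thresholds must be >= 0")
        if self.splice_max_offset < 0 or self.min_case_samples < 0 or self.max_control_samples < 0:
            raise ValueError("thresholds must be >= 0")
        if self.quality_group_rule not in ("any_group", "all_groups"):
            raise ValueError(f"unknown quality_group_rule {self.quality_group_rule!r}")

    def validate_pedigree(self, pedigree: Pedigree) -> None:
        if len(pedigree.cases) < self.min_case_samples:
            raise ValueError(
                f"pedigree has {len(pedigree.cases)} case sample(s) but the genetic "
                f"filter requires at least {self.min_case_samples}")


class CascadeItem(NamedTuple):
    """One (variant record, alternate allele) unit flowing through the cascade."""

    record: VariantRecord
    alt_index: int  # 1-based

    @property
    def key(self) -> VariantKey:
        return self.record.key(self.alt_index)

    @property
    def gene(self) -> str:
        return self.record.gene

    def gene_or_self(self) -> str:
        """Gene symbol, or the variant's own key for gene-less variants."""
        return self.record.gene or f"__variant__{self.key}"


def expand_items(variants: Sequence[VariantRecord]) -> list[CascadeItem]:
    return [CascadeItem(v, j + 1) for v in variants for j in range(len(v.alts))]


def _group_quality_verdict(item: CascadeItem, samples: Sequence[str],
                           threshold: float) -> Optional[bool]:
    """Quality verdict for one pedigree group.

    Returns True/False when the group contains at least one carrier call with
    a non-missing quality (True iff all such qualities reach the threshold),
    or None when the group carries no quality information for this variant.
    """
    quals = [c.quality for s in samples
             if (c := item.record.calls.get(s)) is not None
             and c.is_carrier and c.quality is not None]
    if not quals:
        return None
    return all(q >= threshold for q in quals)


def confidence_filter(items: Sequence[CascadeItem], pedigree: Pedigree,
                      config: CascadeConfig, trace: Optional[FilterTrace] = None
                      ) -> tuple[list[CascadeItem], FilterTrace]:
    """Stage 1: per-group carrier call-quality screen."""
    trace = trace if trace is not None else FilterTrace()
    kept = []
    for item in items:
        verdicts = [_group_quality_verdict(item, g, config.quality_threshold)
                    for g in (pedigree.cases, pedigree.controls)]
        informative = [v for v in verdicts if v is not None]
        if not informative:
            trace.record(item.key, "confidence", False, "no qualified call")
            continue
        ok = any(informative) if config.quality_group_rule == "any_group" else all(informative)
        if ok:
            trace.record(item.key, "confidence", True)
            kept.append(item)
        else:
            trace.record(item.key, "confidence", False,
                         f"carrier call quality below {config.quality_threshold}")
    return kept, trace


def common_variant_filter(items: Sequence[CascadeItem],
                          annotations: Mapping[VariantKey, AnnotationBundle],
                          config: CascadeConfig, trace: Optional[FilterTrace] = None
                          ) -> tuple[list[CascadeItem], FilterTrace]:
    """Stage 2: remove variants common (>= cutoff) in any reference panel."""
    trace = trace if trace is not None else FilterTrace()
    kept = []
    for item in items:
        bundle = annotations.get(item.key)
        freqs = bundle.frequencies if bundle is not None else (None, None, None)
        common_in = [name for name, f in zip(("1kg", "cg69", "esp"), freqs)
                     if f is not None and f >= config.af_cutoff]
        if common_in:
            trace.record(item.key, "common_variants", False,
                         f"allele frequency >= {config.af_cutoff:g} in " + ",".join(common_in))
        else:
            trace.record(item.key, "common_variants", True)
            kept.append(item)
    return kept, trace


def _is_deleterious(bundle: Optional[AnnotationBundle], config: CascadeConfig
                    ) -> tuple[bool, str]:
    if bundle is None:
        return False, "no annotation"
    if bundle.clinical_assertion in KEEP_ASSERTIONS:
        return True, f"clinical assertion {bundle.clinical_assertion}"
    if bundle.gof_literature or bundle.inferred_activating or bundle.bsift_gof:
        return True, "gain-of-function evidence"
    if bundle.mirna_site:
        return True, "microRNA binding site"
    if bundle.consequence in TRUNCATING_CONSEQUENCES:
        return True, f"consequence {bundle.consequence}"
    if bundle.consequence == "missense":
        # missing SIFT does not rescue innocuousness: kept unless tolerated
        if bundle.sift_score is None or bundle.sift_score <= 0.05:
            return True, "missense not predicted innocuous by SIFT"
        return False, f"missense tolerated by SIFT ({bundle.sift_score:g})"
    if bundle.consequence == "splice_region":
        off = bundle.splice_intron_offset
        if off is not None and abs(off) <= config.splice_max_offset:
            return True, f"splice region within {config.splice_max_offset} bases of intron"
        return False, "splice region too deep into intron"
    return False, "no deleteriousness criterion matched"


def deleteriousness_filter(items: Sequence[CascadeItem],
                           annotations: Mapping[VariantKey, AnnotationBundle],
                           config: CascadeConfig, trace: Optional[FilterTrace] = None
                           ) -> tuple[list[CascadeItem], FilterTrace]:
    """Stage 3: keep variants matching any predicted-deleterious criterion."""
    trace = trace if trace is not None else FilterTrace()
    kept = []
    for item in items:
        ok, reason = _is_deleterious(annotations.get(item.key), config)
        trace.record(item.key, "predicted_deleterious", ok, "" if ok else reason)
        if ok:
            kept.append(item)
    return kept, trace


def genetic_model_filter(items: Sequence[CascadeItem], pedigree: Pedigree,
                         config: CascadeConfig, trace: Optional[FilterTrace] = None
                         ) -> tuple[list[CascadeItem], FilterTrace]:
    """Stage 4: autosomal-dominant segregation with gene-level case counting.

    Case carriers are counted over every variant of the gene still in play at
    this stage, so two case samples each heterozygous at *different* variants
    of one gene (a compound-heterozygous pattern) both qualify.  The control
    screen is at the variant level: a variant carried by more than
    ``max_control_samples`` controls is removed regardless of case support.
    """
    trace = trace if trace is not None else FilterTrace()
    config.validate_pedigree(pedigree)
    gene_case_carriers: dict[str, set[str]] = {}
    for item in items:
        carriers = gene_case_carriers.setdefault(item.gene_or_self(), set())
        for s in pedigree.cases:
            call = item.record.calls.get(s)
            if call is not None and call.is_carrier:
                carriers.add(s)
    kept = []
    for item in items:
        n_case = len(gene_case_carriers[item.gene_or_self()])
        control_carriers = [s for s in pedigree.controls
                            if (c := item.record.calls.get(s)) is not None and c.is_carrier]
        if n_case < config.min_case_samples:
            trace.record(item.key, "genetic_analysis", False,
                         f"gene-level case carriers {n_case} < {config.min_case_samples}")
        elif len(control_carriers) > config.max_control_samples:
            trace.record(item.key, "genetic_analysis", False,
                         "carried by control sample(s): " + ",".join(control_carriers))
        else:
            trace.record(item.key, "genetic_analysis", True)
            kept.append(item)
    return kept, trace


def biological_context_filter(items: Sequence[CascadeItem],
                              annotations: Mapping[VariantKey, AnnotationBundle],
                              network: GeneNetwork,
                              trace: Optional[FilterTrace] = None
                              ) -> tuple[list[CascadeItem], FilterTrace]:
    """Stage 5: keep variants whose gene is in, or one hop from, the disease set."""
    trace = trace if trace is not None else FilterTrace()
    kept = []
    for item in items:
        gene = item.gene
        if not gene:
            bundle = annotations.get(item.key)
            gene = bundle.gene if bundle is not None else ""
        if not gene:
            trace.record(item.key, "biological_context", False, "no gene")
        elif network.in_disease_context(gene):
            trace.record(item.key, "biological_context", True)
            kept.append(item)
        else:
            trace.record(item.key, "biological_context", False,
                         f"gene {gene} outside disease context")
    return kept, trace


def run_cascade(variants: Sequence[VariantRecord],
                annotations: Mapping[VariantKey, AnnotationBundle],
                pedigree: Pedigree, network: GeneNetwork,
                config: Optional[CascadeConfig] = None
                ) -> tuple[list[VariantRecord], FilterTrace]:
    """Apply the five stages in order; return kept records and the full trace.

    A multi-allelic record is kept iff at least one of its alternate alleles
    survives.  Conservation (kept = input minus removed) is asserted on the
    trace before returning.
    """
    config = config or CascadeConfig()
    config.validate_pedigree(pedigree)
    items = expand_items(variants)
    trace = FilterTrace()
    items, trace = confidence_filter(items, pedigree, config, trace)
    items, trace = common_variant_filter(items, annotations, config, trace)
    items, trace = deleteriousness_filter(items, annotations, config, trace)
    items, trace = genetic_model_filter(items, pedigree, config, trace)
    items, trace = biological_context_filter(items, annotations, network, trace)
    kept_keys = {item.key for item in items}
    trace.check_conservation([i.key for i in expand_items(variants)], kept_keys)
    kept_records = [v for v in variants
                    if any(v.key(j + 1) in kept_keys for j in range(len(v.alts)))]
    return kept_records, trace
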