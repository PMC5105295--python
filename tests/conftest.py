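import math
from itertools import product

import pytest

from trioprio.synthetic_data import TrioSimSpec, simulate_trio, trio_pedigree, write_trio_bundle
from trioprio.variant_model import AnnotationBundle, GenotypeCall, VariantRecord


def make_trio_variant(chrom="1", pos=1000, ref="A", alt="T", gene="GENE1",
                      father=(0, 0), mother=(0, 1), daughter=(0, 1),
                      quality=(30.0, 30.0, 30.0)):
    """A single-alt trio variant with the study's sample ids.

    ``father``/``mother``/``daughter`` are allele-index pairs (or None for a
    missing call); ``quality`` the matching Phred qualities.
    """
    gts = {"III-1": father, "III-2": mother, "IV-3": daughter}
    calls = {s: GenotypeCall(g, q) for (s, g), q in zip(gts.items(), quality)}
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alts=(alt,), gene=gene,
                         calls=calls)


def rare_deleterious_annotation(gene="GENE1", **overrides):
    """An annotation that passes the frequency and deleteriousness stages."""
    defaults = dict(gene=gene, af_1kg=0.001, consequence="missense", sift_score=0.01)
    defaults.update(overrides)
    return AnnotationBundle(**defaults)


def fisher_2xk_oracle(row1, row2):
    """Brute-force two-sided (minlike) Fisher p on a 2xK table.

    Independent of the package implementation: enumerates every first row
    compatible with the fixed margins and compares exact integer table
    weights C(c1,a1)...C(ck,ak), so probability ties are exact.
    """
    cols = [a + b for a, b in zip(row1, row2)]
    n1 = sum(row1)
    ranges = [range(0, c + 1) for c in cols]
    w_obs = math.prod(math.comb(c, a) for c, a in zip(cols, row1))
    num = 0
    for cells in product(*ranges):
        if sum(cells) != n1:
            continue
        w = math.prod(math.comb(c, a) for c, a in zip(cols, cells))
        if w <= w_obs:
            num += w
    return num / math.comb(sum(cols), n1)


@pytest.fixture(scope="session")
def pedigree():
    return trio_pedigree()


@pytest.fixture(scope="session")
def trio_sim():
    return simulate_trio(TrioSimSpec(n_background=300, seed=11))


@pytest.fixture(scope="session")
def trio_bundle(trio_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return write_trio_bundle(trio_sim, outdir)


def planted_key(sim):
    p = sim.truth["planted"]
    return (p["chrom"], p["pos"], p["ref"], p["alt"])
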