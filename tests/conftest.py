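import numpy as np
import pytest

from mitocompare.genome_io import CircularSequence, FeatureAnnotation, GenomeBundle
from mitocompare.ssr_detect import ScanConfig, classify_ssr, is_primitive


def brute_force_ssrs(s: str, config: ScanConfig | None = None) -> set[tuple[int, str, int]]:
    """Independent SSR enumerator: for every (start, unit length) pair,
    count whole-unit repeats by direct string comparison and keep the
    leftmost-phase, maximal, primitive, tier-passing runs.

    Returns {(1-based start, unit, repeat_count)}.
    """
    config = config or ScanConfig()
    n = len(s)
    found = set()
    for u in range(config.min_unit, config.max_unit + 1):
        for start in range(n - 2 * u + 1):
            unit = s[start : start + u]
            if any(c not in "ACGT" for c in unit):
                continue
            if not is_primitive(unit):
                continue
            k = 1
            while s[start + k * u : start + (k + 1) * u] == unit:
                k += 1
            if classify_ssr(u, k, config) == "rejected":
                continue
            # leftmost phase: the period must break just before the run
            if start >= 1 and s[start - 1] == s[start - 1 + u]:
                continue
            found.add((start + 1, unit, k))
    return found


def random_sequence(rng: np.random.Generator, n: int, at_rich: bool = True) -> str:
    p = [0.42, 0.12, 0.08, 0.38] if at_rich else [0.25] * 4
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture
def toy_bundle() -> GenomeBundle:
    # 60 bp: ND2-like gene at 11..40 (in frame, 30 bp), rest intergenic
    seq = CircularSequence("toy", "ACGTACGTAC" "ATGATTAAACCTGCTTTAGCAACTCTTTAA" "GGGGCCCCTTTTAAAACCCC", True)
    feats = [FeatureAnnotation("nd2", "PCG", "ND2", 11, 40, "+")]
    return GenomeBundle(seq, feats)
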