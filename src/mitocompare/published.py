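"""Published reference values for the three WBPH mitogenomes.

These tables hold the printed results of the original WBPH mitogenome
comparison (accessions MK907866 = WBPHTA, NC_021417 = WBPHHN,
KC512915 = WBPHYN): per-genome composition statistics, the WBPHTA
normal-SSR inventory, the non-common SSR groups, and the pairwise
SNP/INDEL counts. The ``reproduce`` driver compares freshly computed
values against them; nothing here is ever used as a computation result.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["genome_stats", "wbphta_normal_ssrs", "noncommon_groups",
           "PAIRWISE_VARIANTS", "SSR_CENSUS", "GROUP_SUMMARY"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("mitocompare.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def genome_stats() -> pd.DataFrame:
    """Length, GC%, skews and AT-rich-region stats per genome."""
    return _load("wbph_genome_stats.tsv")


def wbphta_normal_ssrs() -> pd.DataFrame:
    """The 25 published normal SSR loci of the WBPHTA mitogenome."""
    df = _load("wbphta_normal_ssrs.tsv")
    return df.fillna({"gene": "Intergenic"})


def noncommon_groups() -> pd.DataFrame:
    """Members of the 5 pairwise and 5 singleton SSR groups."""
    return _load("wbph_ssr_groups_noncommon.tsv")


#: (snps, indel_regions, total_indel_bp) per published genome pair
PAIRWISE_VARIANTS = {
    ("WBPHTA", "WBPHHN"): (21, 4, 9),
    ("WBPHTA", "WBPHYN"): (6, 5, 49),
    ("WBPHHN", "WBPHYN"): (14, 6, 50),
}

#: longest INDEL region (bp), in the control region of the TA-YN pair
LONGEST_INDEL_BP = 42

#: published per-tier census for WBPHTA
SSR_CENSUS = {"normal": 25, "potential": 69, "extended": 9}

#: published cross-genome grouping summary
GROUP_SUMMARY = {"n_groups": 108, "common": 98, "pairwise": 5, "singleton": 5}
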