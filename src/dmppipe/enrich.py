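"""Fisher-exact enrichment of DMPs by chromosome and CGI-relative class.

Chromosomal tests compare the number of hyper- or hypomethylated DMPs on a
chromosome against the array's probe coverage of that chromosome (two-sided
Fisher, raw p at 0.05, BH q reported alongside). Region-class tests do the
same per island/shore/shelf/open-sea class, plus a direction-within-class
test over the DMPs only. A generic gene-set overrepresentation (one-sided
hypergeometric, fold enrichment, BH across categories) covers functional
enrichment on user-supplied sets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import REGION_CLASSES
from .dmp import bh_fdr

__all__ = [
    "fisher_exact_2x2",
    "chromosome_enrichment",
    "region_class_enrichment",
    "direction_proportion_test",
    "overrepresentation",
]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on [[a, b], [c, d]].

    The two-sided p sums hypergeometric point probabilities not exceeding
    that of the observed table (the convention of mainstream
    implementations). Odds ratio is the cross product ad/bc: inf when
    bc = 0 with ad > 0, and NaN (undefined) when a margin is zero, where
    p = 1 by convention (only one table is possible).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return float("nan"), 1.0
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def chromosome_enrichment(
    dmps: pd.DataFrame, manifest: pd.DataFrame, direction: str
) -> pd.DataFrame:
    """Per-chromosome enrichment of DMPs of one direction vs array coverage.

    Table per chromosome c: [[DMPs of ``direction`` on c, elsewhere],
    [array probes on c, elsewhere]]. Returns one row per chromosome present
    in the manifest, with the enriched/depleted call at p < 0.05 by odds
    ratio side. Chromosomes without array probes are skipped with a
    warning.
    """
    if direction not in ("hyper", "hypo", "all"):
        raise ValueError("direction must be 'hyper', 'hypo' or 'all'")
    if dmps.empty:
        return pd.DataFrame(
            columns=["chrom", "a", "b", "c", "d", "odds_ratio", "p_value", "q_value", "call"]
        )
    sel = dmps if direction == "all" else dmps[dmps["direction"] == direction]
    probe_counts = manifest["chrom"].value_counts()
    dmp_counts = sel["chrom"].value_counts()
    total_probes = int(probe_counts.sum())
    total_dmps = int(len(sel))

    rows = []
    for chrom in probe_counts.index:
        n_probes = int(probe_counts[chrom])
        if n_probes == 0:
            warnings.warn(f"chromosome {chrom} has no array probes; skipped", stacklevel=2)
            continue
        a = int(dmp_counts.get(chrom, 0))
        b = total_dmps - a
        c = n_probes
        d = total_probes - n_probes
        odds, p = fisher_exact_2x2(a, b, c, d)
        call = "ns"
        if p < 0.05:
            call = "enriched" if a * d > b * c else "depleted"
        rows.append(
            {"chrom": chrom, "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p_value": p, "call": call}
        )
    out = pd.DataFrame(rows).sort_values("chrom", key=_chrom_sort_key).reset_index(drop=True)
    out.insert(7, "q_value", bh_fdr(out["p_value"].to_numpy()))
    return out


def _chrom_sort_key(s: pd.Series) -> pd.Series:
    order = {f"chr{i}": i for i in range(1, 23)} | {"chrX": 23, "chrY": 24}
    order |= {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24}
    return s.map(lambda c: order.get(str(c), 1000)).astype(int)


def region_class_enrichment(
    annotated_dmps: pd.DataFrame, manifest_classes: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region-class membership and direction-within-class enrichment.

    Parameters
    ----------
    annotated_dmps
        DMP records with region_class and direction columns.
    manifest_classes
        RegionClass per array probe (the background).

    Returns
    -------
    (class_tests, direction_tests)
        ``class_tests``: per class, [[DMPs in class, DMPs outside],
        [array probes in class, outside]]. ``direction_tests``: per class,
        over DMPs only, [[hypo in class, hyper in class],
        [hypo elsewhere, hyper elsewhere]].
    """
    bg = manifest_classes.value_counts()
    total_bg = int(bg.sum())
    n_dmps = len(annotated_dmps)

    class_rows, dir_rows = [], []
    for cls in REGION_CLASSES:
        in_cls = annotated_dmps["region_class"] == cls
        a = int(in_cls.sum())
        b = n_dmps - a
        c = int(bg.get(cls, 0))
        d = total_bg - c
        odds, p = fisher_exact_2x2(a, b, c, d)
        class_rows.append(
            {"region_class": cls, "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p_value": p}
        )
        hypo_in = int((in_cls & (annotated_dmps["direction"] == "hypo")).sum())
        hyper_in = a - hypo_in
        hypo_out = int((annotated_dmps["direction"] == "hypo").sum()) - hypo_in
        hyper_out = b - hypo_out
        odds_d, p_d = fisher_exact_2x2(hypo_in, hyper_in, hypo_out, hyper_out)
        dir_rows.append(
            {
                "region_class": cls,
                "hypo_in": hypo_in,
                "hyper_in": hyper_in,
                "hypo_out": hypo_out,
                "hyper_out": hyper_out,
                "odds_ratio": odds_d,
                "p_value": p_d,
            }
        )
    class_df = pd.DataFrame(class_rows)
    class_df["q_value"] = bh_fdr(class_df["p_value"].to_numpy())
    dir_df = pd.DataFrame(dir_rows)
    dir_df["q_value"] = bh_fdr(dir_df["p_value"].to_numpy())
    return class_df, dir_df


def direction_proportion_test(
    n_hyper: int,
    n_hypo: int,
    mode: str = "binomial_half",
    background: tuple[int, int] | None = None,
) -> float:
    """Test the hyper/hypo split of the DMP set.

    ``binomial_half``: exact two-sided binomial against 0.5 (summing
    outcomes with point probability at most the observed one).
    ``fisher_vs_background``: Fisher test of (n_hyper, n_hypo) against
    background (hyper, hypo) counts.
    """
    if n_hyper < 0 or n_hypo < 0:
        raise ValueError("counts must be non-negative")
    if n_hyper + n_hypo == 0:
        raise ValueError("no DMPs to test")
    if mode == "binomial_half":
        return float(stats.binomtest(n_hyper, n_hyper + n_hypo, 0.5).pvalue)
    if mode == "fisher_vs_background":
        if background is None:
            raise ValueError("fisher_vs_background requires background counts")
        return fisher_exact_2x2(n_hyper, n_hypo, background[0], background[1])[1]
    raise ValueError(f"unknown mode {mode!r}")


def overrepresentation(
    hits: set[str], universe: set[str], categories: dict[str, set[str]]
) -> pd.DataFrame:
    """Gene-set overrepresentation of ``hits`` within ``universe``.

    fold = (k/n) / (K/N) with k = hits in category, n = |hits|,
    K = category size within the universe, N = |universe|; p is the
    one-sided (enrichment) hypergeometric tail; q is BH across categories.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    hits = set(hits) & universe
    n, N = len(hits), len(universe)
    rows = []
    for name, members in categories.items():
        cat = set(members) & universe
        K = len(cat)
        k = len(hits & cat)
        fold = (k / n) / (K / N) if n and K else (0.0 if K else np.nan)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K and n else 1.0
        rows.append({"category": name, "k": k, "n": n, "K": K, "N": N, "fold": fold, "p_value": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out
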