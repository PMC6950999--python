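"""Differential methylation testing: model, results, FDR and stability rule.

The core object is :class:`DifferentialMethylation`, a mass-univariate
two-group model over a beta matrix, in the model/results style of
statsmodels: construct from data, call ``fit()``, get a
:class:`DMPResults` carrying per-probe estimates (delta beta), p/q values,
diagnostics and a ``summary()``.

Calling rules follow the study design they implement: probes are screened
at |delta beta| > 0.1 before FDR (mirroring a dmpFinder-style
betaThreshold), Benjamini-Hochberg q-values are computed over the screened
set, and a probe is emitted as a DMP when q < 0.05 and |delta beta| > 0.15.
``per_stage_intersect`` mode additionally requires the same call with the
same direction at both differentiation stages (the stability rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DifferentialMethylation",
    "DMPResults",
    "probe_test",
    "bh_fdr",
    "call_dmps",
    "stability_filter",
    "cluster_order",
]


class ProbeTestResult(NamedTuple):
    delta_beta: float
    statistic: float
    p_value: float
    degenerate: bool


def probe_test(values_t21, values_ctrl) -> ProbeTestResult:
    """Pooled-variance two-sample t test on one probe's beta values.

    delta_beta = mean(T21) - mean(control); two-sided p with
    df = n1 + n2 - 2. A zero pooled variance is flagged: p = 0 if the
    means differ (infinitely strong evidence under the model), p = 1 if
    they coincide.
    """
    a = np.asarray(values_t21, dtype=float)
    b = np.asarray(values_ctrl, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if ((a < 0) | (a > 1)).any() or ((b < 0) | (b > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    delta = float(a.mean() - b.mean())
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    se = np.sqrt(s2 * (1 / n1 + 1 / n2))
    if se == 0:
        if delta == 0:
            return ProbeTestResult(0.0, 0.0, 1.0, True)
        return ProbeTestResult(delta, np.inf if delta > 0 else -np.inf, 0.0, True)
    t = delta / se
    p = 2 * stats.t.sf(abs(t), df)
    return ProbeTestResult(delta, float(t), float(p), False)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_stats(values: np.ndarray, cols_a: np.ndarray, cols_b: np.ndarray):
    """Vectorised pooled-variance t over all probes (rows)."""
    a, b = values[:, cols_a], values[:, cols_b]
    n1, n2 = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    delta = ma - mb
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / df
    se = np.sqrt(s2 * (1 / n1 + 1 / n2))
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, np.where(delta == 0, 1.0, 0.0), p)
    t = np.where(degenerate, np.where(delta > 0, np.inf, np.where(delta < 0, -np.inf, 0.0)), t)
    return ma, mb, delta, t, p, degenerate


@dataclass
class DMPResults:
    """Fitted per-probe statistics and the emitted DMP set.

    Attributes
    ----------
    table
        Per-probe statistics for every tested probe: group means, delta
        beta, t statistic, p, q (NaN outside the screened set), screening
        and degenerate-variance flags.
    dmps
        Emitted DMP records (q < q_max and |delta beta| > delta_min),
        with direction and stage-consistency flag.
    per_stage
        In ``per_stage_intersect`` mode, the per-stage DMP tables that were
        intersected.
    """

    model: "DifferentialMethylation"
    table: pd.DataFrame
    dmps: pd.DataFrame
    per_stage: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def n_dmps(self) -> int:
        return len(self.dmps)

    @property
    def n_hyper(self) -> int:
        return int((self.dmps["direction"] == "hyper").sum())

    @property
    def n_hypo(self) -> int:
        return int((self.dmps["direction"] == "hypo").sum())

    def summary(self) -> str:
        m = self.model
        lines = [
            "Differential methylation (two-group pooled-variance t)",
            "=" * 56,
            f"mode:            {m.mode}",
            f"probes tested:   {len(self.table)}",
            f"screened (|db| > {m.delta_screen}): {int(self.table['screened'].sum())}",
            f"thresholds:      |delta beta| > {m.delta_min}, q < {m.q_max}",
            f"DMPs called:     {self.n_dmps}  (hyper {self.n_hyper} / hypo {self.n_hypo})",
        ]
        if self.n_dmps:
            top = self.dmps.nsmallest(min(10, self.n_dmps), "q_value")
            lines += ["", "top probes by q:", top.to_string(index=False)]
        return "\n".join(lines)


class DifferentialMethylation:
    """Two-group (T21 vs control) differential methylation model.

    Parameters
    ----------
    beta
        Probes x samples beta matrix (values in [0, 1]).
    sample_sheet
        One row per sample with columns sample_id, group in {T21, control},
        stage in {NPC, DiffNPC}. Only samples listed here are used, so the
        fit is invariant to the column order of ``beta``.
    delta_screen
        |delta beta| pre-screen applied before FDR.
    delta_min
        Minimum |delta beta| for an emitted DMP.
    q_max
        FDR threshold for an emitted DMP.
    mode
        ``pooled`` tests all T21 samples against all controls (both stages
        together); ``per_stage_intersect`` calls DMPs within each stage and
        keeps probes significant in both with the same direction.
    """

    def __init__(
        self,
        beta: pd.DataFrame,
        sample_sheet: pd.DataFrame,
        *,
        delta_screen: float = 0.1,
        delta_min: float = 0.15,
        q_max: float = 0.05,
        mode: str = "pooled",
    ) -> None:
        if mode not in ("pooled", "per_stage_intersect"):
            raise ValueError(f"unknown mode {mode!r}")
        missing = set(sample_sheet["sample_id"]) - set(beta.columns)
        if missing:
            raise ValueError(f"samples missing from beta matrix: {sorted(missing)}")
        self.beta = beta
        self.sheet = sample_sheet.reset_index(drop=True)
        self.delta_screen = float(delta_screen)
        self.delta_min = float(delta_min)
        self.q_max = float(q_max)
        self.mode = mode

    @classmethod
    def from_dataframe(cls, beta: pd.DataFrame, sample_sheet: pd.DataFrame, **kwargs) -> "DifferentialMethylation":
        return cls(beta, sample_sheet, **kwargs)

    def _fit_contrast(self, sheet: pd.DataFrame) -> pd.DataFrame:
        cols = list(self.beta.columns)
        t21 = sheet.loc[sheet["group"] == "T21", "sample_id"]
        ctrl = sheet.loc[sheet["group"] == "control", "sample_id"]
        if len(t21) < 2 or len(ctrl) < 2:
            raise ValueError("need at least 2 samples per group in the contrast")
        values = self.beta.to_numpy(dtype=float)
        ia = np.array([cols.index(s) for s in t21])
        ib = np.array([cols.index(s) for s in ctrl])
        ma, mb, delta, t, p, degenerate = _group_stats(values, ia, ib)
        tab = pd.DataFrame(
            {
                "probe_id": self.beta.index,
                "mean_T21": ma,
                "mean_ctrl": mb,
                "delta_beta": delta,
                "statistic": t,
                "p_value": p,
                "degenerate_variance": degenerate,
            }
        )
        tab["screened"] = tab["delta_beta"].abs() > self.delta_screen
        tab["q_value"] = np.nan
        sel = tab["screened"].to_numpy()
        if sel.any():
            tab.loc[sel, "q_value"] = bh_fdr(tab.loc[sel, "p_value"].to_numpy())
        return tab

    @staticmethod
    def _emit(tab: pd.DataFrame, delta_min: float, q_max: float) -> pd.DataFrame:
        keep = (tab["q_value"] < q_max) & (tab["delta_beta"].abs() > delta_min)
        dmps = tab.loc[keep.fillna(False)].copy()
        dmps["direction"] = np.where(dmps["delta_beta"] > 0, "hyper", "hypo")
        dmps["stage_consistent"] = False
        return dmps.reset_index(drop=True)

    def fit(self) -> DMPResults:
        if self.mode == "pooled":
            tab = self._fit_contrast(self.sheet)
            dmps = self._emit(tab, self.delta_min, self.q_max)
            return DMPResults(self, tab, dmps)

        per_stage_tab: dict[str, pd.DataFrame] = {}
        per_stage_dmps: dict[str, pd.DataFrame] = {}
        for stage, sub in self.sheet.groupby("stage", sort=True):
            for grp in ("T21", "control"):
                if (sub["group"] == grp).sum() < 2:
                    raise ValueError(
                        f"per_stage_intersect needs >=2 samples per group per stage; "
                        f"stage {stage!r} group {grp!r} has fewer"
                    )
            tab = self._fit_contrast(sub)
            per_stage_tab[stage] = tab
            per_stage_dmps[stage] = self._emit(tab, self.delta_min, self.q_max)
        stages = sorted(per_stage_tab)
        stable = stability_filter(per_stage_dmps[stages[0]], per_stage_dmps[stages[1]])
        # report pooled per-probe stats as the reference table
        pooled_tab = self._fit_contrast(self.sheet)
        return DMPResults(self, pooled_tab, stable, per_stage=per_stage_tab)


def call_dmps(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    delta_screen: float = 0.1,
    delta_min: float = 0.15,
    q_max: float = 0.05,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Functional wrapper: fit the model and return the emitted DMP table."""
    model = DifferentialMethylation(
        beta, sheet, delta_screen=delta_screen, delta_min=delta_min, q_max=q_max, mode=mode
    )
    return model.fit().dmps


def stability_filter(dmps_stage1: pd.DataFrame, dmps_stage2: pd.DataFrame) -> pd.DataFrame:
    """Keep probes called in both stages with the same direction.

    delta_beta (and group means) are reported as the mean over the two
    stages; p and q conservatively as the per-stage maximum.
    """
    if dmps_stage1.empty or dmps_stage2.empty:
        return dmps_stage1.iloc[0:0].assign(stage_consistent=True)
    merged = dmps_stage1.merge(dmps_stage2, on="probe_id", suffixes=("_1", "_2"))
    merged = merged[merged["direction_1"] == merged["direction_2"]]
    if merged.empty:
        return dmps_stage1.iloc[0:0].assign(stage_consistent=True)
    out = pd.DataFrame(
        {
            "probe_id": merged["probe_id"],
            "mean_T21": (merged["mean_T21_1"] + merged["mean_T21_2"]) / 2,
            "mean_ctrl": (merged["mean_ctrl_1"] + merged["mean_ctrl_2"]) / 2,
            "delta_beta": (merged["delta_beta_1"] + merged["delta_beta_2"]) / 2,
            "statistic": merged[["statistic_1", "statistic_2"]].apply(
                lambda r: r.iloc[0] if abs(r.iloc[0]) < abs(r.iloc[1]) else r.iloc[1], axis=1
            ),
            "p_value": merged[["p_value_1", "p_value_2"]].max(axis=1),
            "q_value": merged[["q_value_1", "q_value_2"]].max(axis=1),
            "degenerate_variance": merged["degenerate_variance_1"] | merged["degenerate_variance_2"],
            "screened": True,
            "direction": merged["direction_1"],
            "stage_consistent": True,
        }
    )
    return out.reset_index(drop=True)


def cluster_order(beta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic hierarchical-clustering leaf orders (rows, columns).

    Euclidean distance, average linkage; scipy's linkage breaks distance
    ties by cluster index (lower first), so the result is reproducible.
    Single-row (or single-column) inputs return the trivial order.
    """
    def _order(mat: np.ndarray) -> np.ndarray:
        if mat.shape[0] < 2:
            return np.arange(mat.shape[0])
        return leaves_list(linkage(mat, method="average", metric="euclidean"))

    values = beta.to_numpy(dtype=float)
    return _order(values), _order(values.T)
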