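"""Synthetic 450K-style methylation-array data with planted group effects.

The generator emulates the statistical frame of an Infinium 450K experiment
on a two-group (trisomy-21 vs euploid control), two-stage (neural progenitor
vs 30-day differentiated) design: a probe manifest laid out around CpG
islands and gene models, per-sample beta values drawn from a bimodal
mixture, a chosen probe subset carrying direction-consistent group
differences, and raw intensity pairs with occasional detection failures.
Every planted effect is recorded in a truth table so recovery can be scored
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChromSpec",
    "PlantingSpec",
    "MixtureSpec",
    "default_sample_sheet",
    "generate_manifest",
    "generate_dataset",
    "generate_intensities",
]

STAGES = ("NPC", "DiffNPC")
GROUPS = ("T21", "control")

# baseline probe layout relative to CpG islands; remainder is placed
# uniformly (mostly open sea)
DEFAULT_REGION_FRACTIONS = {"island": 0.31, "shore": 0.23, "shelf": 0.10}


@dataclass(frozen=True)
class ChromSpec:
    """A chromosome of the synthetic genome."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r} must have positive length")


@dataclass(frozen=True)
class MixtureSpec:
    """Two-component beta mixture for baseline probe methylation.

    Array-wide beta values are bimodal: a mostly-unmethylated mode (CpG
    islands in promoters) and a mostly-methylated mode (gene bodies, open
    sea). ``concentration`` controls the spread of each mode.
    """

    low_mode: float = 0.10
    high_mode: float = 0.85
    weight_low: float = 0.5
    concentration: float = 25.0

    def __post_init__(self) -> None:
        if not (0 < self.low_mode < self.high_mode < 1):
            raise ValueError("modes must satisfy 0 < low < high < 1")
        if not 0 <= self.weight_low <= 1:
            raise ValueError("weight_low must be in [0, 1]")
        if self.concentration <= 2:
            raise ValueError("concentration must exceed 2")


@dataclass(frozen=True)
class PlantingSpec:
    """How group-consistent differential methylation is planted.

    Parameters
    ----------
    n_planted
        Number of probes carrying a true group effect.
    delta_mean
        Target |delta beta| (T21 minus control group mean), as a fraction.
        Defaults above the 0.15 calling threshold so planted probes are
        recoverable in principle.
    delta_sd
        Spread of per-probe |delta beta| around ``delta_mean`` (truncated so
        every planted effect stays above 0.16).
    direction_mix
        Fraction of planted probes that are hypomethylated in T21.
    consistent_across_stages
        If True (default) the same effect is present at both differentiation
        stages; if False it is planted at the first stage only.
    probe_ids
        Optional explicit probe subset to plant on (overrides random
        selection; ``n_planted`` is then taken from its length).
    """

    n_planted: int = 500
    delta_mean: float = 0.30
    delta_sd: float = 0.04
    direction_mix: float = 0.5
    consistent_across_stages: bool = True
    probe_ids: Sequence[str] | None = field(default=None)

    def __post_init__(self) -> None:
        if not 0 < self.delta_mean < 1:
            raise ValueError("delta_mean must be in (0, 1)")
        if not 0 <= self.direction_mix <= 1:
            raise ValueError("direction_mix must be in [0, 1]")
        if self.delta_sd < 0:
            raise ValueError("delta_sd must be non-negative")
        if self.n_planted < 0:
            raise ValueError("n_planted must be non-negative")


def default_sample_sheet() -> pd.DataFrame:
    """The study-like design: 2 donors x 2 groups x 2 stages = 8 samples.

    Pooling stages gives the 4-vs-4 contrast (T21 vs control).
    """
    rows = []
    for stage in STAGES:
        for group, prefix in (("T21", "DS"), ("control", "Ctrl")):
            for donor in (1, 2):
                rows.append(
                    {
                        "sample_id": f"{prefix}{donor}_{stage}",
                        "group": group,
                        "stage": stage,
                    }
                )
    return pd.DataFrame(rows)


def _place_intervals(
    rng: np.random.Generator,
    chrom_length: int,
    lengths: np.ndarray,
    min_gap: int,
) -> np.ndarray:
    """Place non-overlapping intervals of given lengths on [1, chrom_length].

    Returns start coordinates (1-based). Raises if they cannot fit.
    """
    n = len(lengths)
    if n == 0:
        return np.array([], dtype=int)
    occupied = int(lengths.sum()) + (n - 1) * min_gap
    slack = chrom_length - occupied
    if slack < 0:
        raise ValueError(
            f"cannot place {n} intervals (total {occupied} bp with gaps) "
            f"on a chromosome of {chrom_length} bp"
        )
    # distribute the slack over n+1 gaps
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    extra = np.diff(np.concatenate(([0], cuts)))
    starts = np.empty(n, dtype=int)
    pos = 1
    for i in range(n):
        pos += extra[i]
        starts[i] = pos
        pos += int(lengths[i]) + min_gap
    return starts


def generate_manifest(
    n_probes: int,
    chroms: Sequence[ChromSpec],
    cgi_density: float = 9.0,
    genes_per_chrom: int = 300,
    seed: int = 0,
    region_fractions: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a probe manifest plus CpG-island and gene-model tables.

    Parameters
    ----------
    n_probes
        Total probes on the synthetic array.
    chroms
        Chromosome names and lengths (bp).
    cgi_density
        CpG islands per megabase.
    genes_per_chrom
        Gene models per chromosome.
    region_fractions
        Target fractions of probes placed inside islands / in shores /
        in shelves; the remainder is placed uniformly.

    Returns
    -------
    (manifest, cgis, genes)
        ``manifest``: probe_id, chrom, pos (1-based), strand, design_type,
        sorted by (chrom, pos). ``cgis``: chrom, start, end (1-based
        inclusive), cgi_id. ``genes``: name, chrom, strand, tx bounds,
        first-exon bounds, CDS bounds.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    names = [c.name for c in chroms]
    if len(set(names)) != len(names):
        raise ValueError("chromosome names must be unique")
    fractions = dict(DEFAULT_REGION_FRACTIONS if region_fractions is None else region_fractions)
    if sum(fractions.values()) > 1 + 1e-9:
        raise ValueError("region fractions must sum to at most 1")

    rng = np.random.default_rng(seed)
    total_len = sum(c.length for c in chroms)

    cgi_rows, gene_rows = [], []
    islands_by_chrom: dict[str, np.ndarray] = {}
    for spec in chroms:
        n_islands = int(round(cgi_density * spec.length / 1e6))
        lengths = rng.integers(300, 1501, size=n_islands)
        starts = _place_intervals(rng, spec.length, lengths, min_gap=9000)
        islands_by_chrom[spec.name] = np.column_stack([starts, starts + lengths - 1]) if n_islands else np.empty((0, 2), int)
        for i, (s, ln) in enumerate(zip(starts, lengths)):
            cgi_rows.append(
                {"chrom": spec.name, "start": int(s), "end": int(s + ln - 1), "cgi_id": f"CGI_{spec.name}_{i + 1}"}
            )
        # most gene promoters sit at a CpG island, as in real genomes
        glengths = rng.integers(5_000, 50_001, size=genes_per_chrom)
        for i, ln in enumerate(glengths):
            ln = int(ln)
            strand = "+" if rng.random() < 0.5 else "-"
            islands = islands_by_chrom[spec.name]
            if len(islands) and rng.random() < 0.7:
                s0, e0 = islands[rng.integers(len(islands))]
                jitter = int(rng.integers(-300, 301))
                if strand == "+":
                    tx_start = int(s0) + jitter
                else:
                    tx_start = int(e0) + jitter - ln + 1
            else:
                tx_start = int(rng.integers(1, max(spec.length - ln, 1) + 1))
            tx_start = min(max(tx_start, 1), max(spec.length - ln, 1))
            tx_end = tx_start + ln - 1
            exon_len = int(rng.integers(100, 501))
            utr3_len = int(rng.integers(100, 2001))
            cds_offset = int(rng.integers(30, exon_len))
            if strand == "+":
                fe_start, fe_end = tx_start, tx_start + exon_len - 1
                cds_start = tx_start + cds_offset
                cds_end = tx_end - utr3_len
            else:
                fe_start, fe_end = tx_end - exon_len + 1, tx_end
                cds_end = tx_end - cds_offset
                cds_start = tx_start + utr3_len
            gene_rows.append(
                {
                    "name": f"G{spec.name.lstrip('chr')}_{i + 1:04d}",
                    "chrom": spec.name,
                    "strand": strand,
                    "tx_start": tx_start,
                    "tx_end": tx_end,
                    "first_exon_start": fe_start,
                    "first_exon_end": fe_end,
                    "cds_start": min(cds_start, cds_end),
                    "cds_end": max(cds_start, cds_end),
                }
            )

    # probe placement: island / shore / shelf targets, remainder uniform
    p_island = fractions.get("island", 0.0)
    p_shore = fractions.get("shore", 0.0)
    p_shelf = fractions.get("shelf", 0.0)
    chrom_p = np.array([c.length / total_len for c in chroms])
    kind = rng.choice(4, size=n_probes, p=[p_island, p_shore, p_shelf, 1 - p_island - p_shore - p_shelf])
    chrom_idx = rng.choice(len(chroms), size=n_probes, p=chrom_p)
    pos = np.empty(n_probes, dtype=int)
    for i in range(n_probes):
        spec = chroms[chrom_idx[i]]
        islands = islands_by_chrom[spec.name]
        k = kind[i] if len(islands) else 3
        if k == 3:
            pos[i] = int(rng.integers(1, spec.length + 1))
            continue
        s, e = islands[rng.integers(len(islands))]
        if k == 0:
            pos[i] = int(rng.integers(s, e + 1))
        else:
            lo, hi = (1, 2000) if k == 1 else (2001, 4000)
            d = int(rng.integers(lo, hi + 1))
            p = s - d if rng.random() < 0.5 else e + d
            pos[i] = int(min(max(p, 1), spec.length))

    manifest = pd.DataFrame(
        {
            "chrom": [chroms[j].name for j in chrom_idx],
            "pos": pos,
            "strand": rng.choice(["+", "-"], size=n_probes),
            "design_type": rng.choice(["I", "II"], size=n_probes, p=[0.28, 0.72]),
        }
    )
    order = {c.name: i for i, c in enumerate(chroms)}
    manifest["_rank"] = manifest["chrom"].map(order)
    manifest = manifest.sort_values(["_rank", "pos"], kind="mergesort").drop(columns="_rank")
    manifest.insert(0, "probe_id", [f"cg{i:08d}" for i in range(1, n_probes + 1)])
    manifest = manifest.reset_index(drop=True)

    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "cgi_id"])
    genes = pd.DataFrame(gene_rows)
    return manifest, cgis, genes


def _draw_base_mean(rng: np.random.Generator, mixture: MixtureSpec, size: int) -> np.ndarray:
    comp = rng.random(size) < mixture.weight_low
    mode = np.where(comp, mixture.low_mode, mixture.high_mode)
    c = mixture.concentration
    return rng.beta(mode * c, (1 - mode) * c)


def generate_dataset(
    manifest: pd.DataFrame,
    sheet: pd.DataFrame,
    planting: PlantingSpec,
    mixture: MixtureSpec | None = None,
    precision: float = 200.0,
    seed: int = 0,
    clamp: tuple[float, float] = (0.02, 0.98),
    type2_shift: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a beta matrix with planted group effects and its truth table.

    Unplanted probes share a group-independent mean drawn from the bimodal
    mixture; planted probes get T21 and control group means separated by a
    signed ``true_delta``. Per-sample values are beta-distributed around the
    probe/group mean with the given precision (mean--precision
    parameterisation), which keeps everything in [0, 1] without truncation.

    Planted probes draw their baseline conditioned on the planted direction
    so that the effect fits inside ``clamp`` (a probe must have methylation
    to lose before it can be hypomethylated); user-forced extremes are still
    clamped, with a warning.

    ``type2_shift`` adds a group-independent mean shift to type-II probes
    (no type-specific chemistry beyond this is simulated); it exists to
    exercise the within-array normalization stage.
    """
    mixture = mixture or MixtureSpec()
    rng = np.random.default_rng(seed)
    if not {"T21", "control"} <= set(sheet["group"]):
        raise ValueError("sample sheet must contain both groups")
    if not set(STAGES) <= set(sheet["stage"]):
        raise ValueError("sample sheet must contain both stages")

    probe_ids = manifest["probe_id"].to_numpy()
    n = len(probe_ids)
    if planting.probe_ids is not None:
        planted_ids = np.asarray(list(planting.probe_ids))
        missing = set(planted_ids) - set(probe_ids)
        if missing:
            raise ValueError(f"planted probe ids not in manifest: {sorted(missing)[:5]}")
        n_planted = len(planted_ids)
    else:
        n_planted = planting.n_planted
        if n_planted > n:
            raise ValueError("n_planted exceeds number of probes")
        planted_ids = rng.choice(probe_ids, size=n_planted, replace=False)

    base_mean = _draw_base_mean(rng, mixture, n)
    idx = pd.Index(probe_ids)
    planted_pos = idx.get_indexer(planted_ids)

    lo, hi = clamp
    hypo = rng.random(n_planted) < planting.direction_mix
    mags = rng.normal(planting.delta_mean, planting.delta_sd, size=n_planted)
    mags = np.clip(mags, 0.16, 0.95)
    deltas = np.where(hypo, -mags, mags)

    # baseline conditioned on direction headroom (rejection sampling)
    clamped = 0
    for j, (pi, d) in enumerate(zip(planted_pos, deltas)):
        m = base_mean[pi]
        for _ in range(200):
            if lo <= m + d <= hi and lo <= m <= hi:
                break
            m = _draw_base_mean(rng, mixture, 1)[0]
        base_mean[pi] = m
        if not (lo <= m + d <= hi):
            clamped += 1
    if clamped:
        warnings.warn(f"{clamped} planted effects clamped to [{lo}, {hi}]", stacklevel=2)

    if type2_shift and "design_type" in manifest.columns:
        is_two = (manifest["design_type"] == "II").to_numpy()
        base_mean[is_two] = np.clip(base_mean[is_two] + type2_shift, 1e-3, 1 - 1e-3)

    ctrl_mean = base_mean.copy()
    t21_mean = base_mean.copy()
    t21_mean[planted_pos] = np.clip(t21_mean[planted_pos] + deltas, lo, hi)
    realized = t21_mean[planted_pos] - ctrl_mean[planted_pos]

    cols = {}
    first_stage = STAGES[0]
    for _, row in sheet.iterrows():
        active = planting.consistent_across_stages or row["stage"] == first_stage
        mean = t21_mean if (row["group"] == "T21" and active) else ctrl_mean
        m = np.clip(mean, 1e-3, 1 - 1e-3)
        cols[row["sample_id"]] = rng.beta(m * precision, (1 - m) * precision)
    beta = pd.DataFrame(cols, index=idx)
    beta.index.name = "probe_id"

    truth = pd.DataFrame(
        {
            "probe_id": planted_ids,
            "true_delta": realized,
            "true_direction": np.where(deltas < 0, "hypo", "hyper"),
        }
    )
    return beta, truth


def generate_intensities(
    beta: pd.DataFrame,
    total_mean: float = 4000.0,
    fail_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Back-generate methylated/unmethylated intensity pairs from betas.

    Total intensity per cell is gamma-distributed around ``total_mean`` and
    split as M = beta * total, U = total - M, so recomputing beta with
    offset o incurs a bias of at most o / (M + U + o). A ``fail_rate``
    fraction of cells is marked as detection failures (detection p >= 0.01,
    attenuated signal); passing cells get detection p < 0.01.
    """
    if not 0 <= fail_rate <= 0.05:
        raise ValueError("fail_rate must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    shape = beta.shape
    total = rng.gamma(20.0, total_mean / 20.0, size=shape)
    total = np.maximum(total, 200.0)
    b = beta.to_numpy()
    m = b * total
    u = total - m
    failed = rng.random(shape) < fail_rate
    detp = rng.uniform(0.0, 0.005, size=shape)
    detp[failed] = rng.uniform(0.01, 0.6, size=int(failed.sum()))
    m = np.where(failed, m * 0.05, m)
    u = np.where(failed, u * 0.05, u)
    wrap = lambda a: pd.DataFrame(a, index=beta.index, columns=beta.columns)
    return wrap(m), wrap(u), wrap(detp)
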