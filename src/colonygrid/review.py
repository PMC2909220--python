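"""Data review: normalization, exclusion heuristics and screen statistics.

Raw colony areas are made comparable across plates by dividing each value by
its plate's median (robust to blank positions), or by the median of
designated control positions when most strains are expected to respond.

Two automated exclusion heuristics then flag spurious positions:

* **global** — un-inoculated plate sections.  A colony is excluded when it
  is itself below the low-growth threshold (25% of the plate median) and
  either at least 6 of its 8 Moore neighbors are below that threshold, or at
  least 2 neighbors have already been excluded; the rule is iterated to a
  fixed point so exclusion creeps from the dead core out to its boundary.
* **replicate** — on quad-replicate plates (each strain as a 2x2 block), a
  colony deviating from its block median by more than 45% of that median is
  excluded.

Per-strain significance comes from one of three tests chosen by the user:
z-scores against the screen-wide distribution of log growth ratios
(self-correcting for multiplicity by construction), Welch's unequal-variance
t-test between replicate sets, or the Mann-Whitney U test with exact
enumeration up to 20 samples.  Bonferroni correction is available for the
latter two.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, NormalizationError, PairingError
from .formats import (
    GridFormat, MeasurementTable, PlateKey, STATS_COLUMNS, join_key,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationConfig", "ExclusionParams", "StatConfig", "ReviewedDataset",
    "normalize", "exclude_global", "exclude_replicates", "strain_ratios",
    "pvalues_normal", "pvalues_welch", "pvalues_mannwhitney", "bonferroni",
    "shimazaki_bin_width", "review_pipeline",
]


@dataclass(frozen=True)
class NormalizationConfig:
    method: str = "plate_median"     # plate_median | designated_controls | none

    def __post_init__(self) -> None:
        if self.method not in ("plate_median", "designated_controls", "none"):
            raise ConfigError(f"unknown normalization method {self.method!r}")


@dataclass(frozen=True)
class ExclusionParams:
    """Tunables of the two exclusion heuristics (defaults are the optimized
    values: 6 low neighbors / 2 excluded neighbors, 45% replicate band)."""

    low_growth_fraction: float = 0.25
    neighbor_low_count: int = 6
    neighbor_excluded_count: int = 2
    replicate_band: float = 0.45
    enable_global: bool = True
    enable_replicate: bool = True
    literal_within_band: bool = False   # historical literal reading of the band

    def __post_init__(self) -> None:
        if not 0 < self.low_growth_fraction < 1:
            raise ConfigError("low_growth_fraction must be in (0, 1)")
        if not 1 <= self.neighbor_low_count <= 8:
            raise ConfigError("neighbor_low_count must be in 1..8")
        if not 1 <= self.neighbor_excluded_count <= 8:
            raise ConfigError("neighbor_excluded_count must be in 1..8")
        if not 0 < self.replicate_band < 1:
            raise ConfigError("replicate_band must be in (0, 1)")


@dataclass(frozen=True)
class StatConfig:
    test: str = "normal_distribution"   # normal_distribution | welch_t | mann_whitney
    bonferroni: bool = False
    p_threshold: float = 0.05
    log_base: float = math.e
    population_sd: bool = True          # population (ddof=0) vs sample SD for z

    def __post_init__(self) -> None:
        if self.test not in ("normal_distribution", "welch_t", "mann_whitney"):
            raise ConfigError(f"unknown test {self.test!r}")
        if self.test == "normal_distribution" and self.bonferroni:
            raise ConfigError(
                "Bonferroni must not be combined with the normal-distribution "
                "method; its p-values are rank-based and already corrected"
            )
        if not 0 < self.p_threshold <= 1:
            raise ConfigError("p_threshold must be in (0, 1]")


@dataclass
class ReviewedDataset:
    """Normalized values, masks and per-strain statistics of one review run."""

    data: pd.DataFrame                   # per-position records incl. masks
    stats: pd.DataFrame                  # per-strain StrainStats rows
    norm_config: NormalizationConfig
    excl_params: ExclusionParams
    stat_config: StatConfig


# ---------------------------------------------------------------------------
# normalization


def _median(values: np.ndarray) -> float:
    """Median with the documented even-count convention (mean of middle two)."""
    return float(np.median(values))


def normalize(table: MeasurementTable, config: NormalizationConfig,
              key: PlateKey | None = None) -> MeasurementTable:
    """Divide each value by its plate's (or its plate controls') median.

    Every (plate, condition) group is one physical plate image.  A zero
    divisor raises :class:`NormalizationError` naming the plate; designated
    controls are looked up in *key* (required for that method).
    """
    df = table.data.copy()
    if config.method == "none":
        return MeasurementTable(df)
    if config.method == "designated_controls":
        if key is None and "control" not in df.columns:
            raise ConfigError("designated_controls normalization requires a key")
        if "control" not in df.columns:
            df = join_key(MeasurementTable(df), key).data

    out = []
    for (plate, cond), grp in df.groupby(["plate", "condition"], sort=False):
        if config.method == "plate_median":
            divisor = _median(grp["value"].to_numpy())
        else:
            ctrl = grp.loc[grp["control"].astype(bool), "value"].to_numpy()
            if ctrl.size == 0:
                raise ConfigError(
                    f"plate {plate!r}/{cond!r} has no designated controls"
                )
            divisor = _median(ctrl)
        if divisor == 0:
            raise NormalizationError(
                f"plate {plate!r} condition {cond!r}: zero median divisor"
            )
        g = grp.copy()
        g["value"] = g["value"] / divisor
        out.append(g)
    return MeasurementTable(pd.concat(out, ignore_index=True))


def plate_grid(df: pd.DataFrame, fmt: GridFormat) -> np.ndarray:
    """rows x cols value array of one plate's records (NaN where absent)."""
    grid = np.full(fmt.shape, np.nan)
    grid[df["row"].to_numpy() - 1, df["col"].to_numpy() - 1] = df["value"].to_numpy()
    return grid


# ---------------------------------------------------------------------------
# exclusion heuristics


def _neighbor_counts(mask: np.ndarray) -> np.ndarray:
    """Count of True Moore neighbors for each cell (edge-aware)."""
    m = mask.astype(int)
    p = np.pad(m, 1)
    out = (p[:-2, :-2] + p[:-2, 1:-1] + p[:-2, 2:]
           + p[1:-1, :-2] + p[1:-1, 2:]
           + p[2:, :-2] + p[2:, 1:-1] + p[2:, 2:])
    return out


def _existing_neighbors(shape: tuple[int, int]) -> np.ndarray:
    ones = np.ones(shape, dtype=int)
    return _neighbor_counts(ones.astype(bool))


def exclude_global(plate: np.ndarray, params: ExclusionParams | None = None
                   ) -> np.ndarray:
    """Fixed point of the recursive dead-section exclusion rule.

    *plate* is a rows x cols array of plate-median-normalized values.  A
    colony is excluded iff it is itself low (< ``low_growth_fraction``) and
    (>= 6 of its existing neighbors are low) or (>= 2 of its existing
    neighbors are already excluded); both neighbor thresholds scale
    proportionally at plate borders (ceil(p * k / 8) of k existing
    neighbors).  Synchronous sweeps are iterated until no new exclusions.
    """
    params = params or ExclusionParams()
    vals = np.asarray(plate, dtype=float)
    low = np.nan_to_num(vals, nan=np.inf) < params.low_growth_fraction
    k = _existing_neighbors(vals.shape)
    thr_low = np.ceil(params.neighbor_low_count * k / 8.0)
    thr_exc = np.ceil(params.neighbor_excluded_count * k / 8.0)
    low_nb = _neighbor_counts(low)

    excluded = np.zeros(vals.shape, dtype=bool)
    while True:
        exc_nb = _neighbor_counts(excluded)
        new = low & ((low_nb >= thr_low) | (exc_nb >= thr_exc)) & ~excluded
        if not new.any():
            return excluded
        excluded |= new


def exclude_replicates(plate: np.ndarray, fmt: GridFormat,
                       params: ExclusionParams | None = None) -> np.ndarray:
    """Quad-replicate outlier exclusion on 2x2 strain blocks.

    Only runs for ``replicate_layout == "quad_2x2"``; other layouts return
    an empty mask with a warning.  A colony is excluded when its value
    deviates from the block median by more than ``replicate_band`` of that
    median (the literal "within the band" reading is available via
    ``literal_within_band``).
    """
    params = params or ExclusionParams()
    vals = np.asarray(plate, dtype=float)
    mask = np.zeros(vals.shape, dtype=bool)
    if fmt.replicate_layout != "quad_2x2":
        warnings.warn("replicate exclusion requires a quad_2x2 layout; skipped")
        return mask
    for i in range(0, fmt.rows, 2):
        for j in range(0, fmt.cols, 2):
            block = vals[i:i + 2, j:j + 2]
            med = _median(block.ravel())
            dev = np.abs(block - med)
            if params.literal_within_band:
                bad = dev <= params.replicate_band * abs(med)
            else:
                bad = dev > params.replicate_band * abs(med)
            mask[i:i + 2, j:j + 2] = bad
    return mask


# ---------------------------------------------------------------------------
# per-strain ratios and tests


def strain_ratios(control: pd.DataFrame, experimental: pd.DataFrame,
                  log_base: float = math.e) -> pd.DataFrame:
    """Per-strain means and growth/log ratios from two annotated plates.

    Inputs are per-position records with columns ``strain, orf, value,
    excluded`` (and position columns).  Excluded replicates are omitted from
    the means; strains with no surviving replicate on either side are
    flagged (NaN means) rather than tested.  ``growth_ratio`` is
    experimental/control; ``log_ratio`` is log(control/experimental), +inf
    when the strain is dead on the experimental plate.
    """
    def collapse(df: pd.DataFrame, prefix: str) -> pd.DataFrame:
        kept = df[~df["excluded"].astype(bool)]
        g = kept.groupby("strain")["value"].agg(["mean", "count"])
        g.columns = [f"{prefix}_mean", f"n_{prefix}"]
        all_n = df.groupby("strain").agg(
            orf=("orf", "first"), plate=("plate", "first"),
            total=("value", "size"),
            positions=("row", lambda r: ";".join(
                f"{a},{b}" for a, b in zip(r, df.loc[r.index, "col"]))),
        )
        return all_n.join(g)

    c = collapse(control, "control")
    e = collapse(experimental, "experimental")[
        ["experimental_mean", "n_experimental", "total"]
    ].rename(columns={"total": "total_e"})
    m = c.join(e, how="outer")
    m["n_control"] = m["n_control"].fillna(0).astype(int)
    m["n_experimental"] = m["n_experimental"].fillna(0).astype(int)
    m["excluded_count"] = (
        (m["total"].fillna(0) - m["n_control"])
        + (m["total_e"].fillna(0) - m["n_experimental"])
    ).astype(int)

    cm = m["control_mean"].to_numpy(dtype=float)
    em = m["experimental_mean"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        growth = em / cm
        logr = np.log(cm / em) / math.log(log_base)
    logr[(em == 0) & (cm > 0)] = np.inf       # dead on experimental
    m["growth_ratio"] = growth
    m["log_ratio"] = logr
    return m.drop(columns=["total", "total_e"]).reset_index()


def pvalues_normal(log_ratios: np.ndarray, population_sd: bool = True
                   ) -> tuple[np.ndarray, np.ndarray]:
    """z-scores and two-tailed normal p-values against the screen population.

    Non-finite ratios (dead strains) are ignored when fitting the mean/SD
    and get NaN scores.  Requires >= 3 finite ratios with nonzero spread.
    """
    x = np.asarray(log_ratios, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("need at least 3 finite log ratios")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=0 if population_sd else 1)
    if sd == 0:
        raise ValueError("degenerate population: zero standard deviation")
    z = np.where(finite, (x - mu) / sd, np.nan)
    p = np.clip(2.0 * sps.norm.sf(np.abs(z)), 0.0, 1.0)
    return z, p


def pvalues_welch(control_reps: np.ndarray, exp_reps: np.ndarray
                  ) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, df, two-tailed p).

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with the Welch-Satterthwaite
    degrees of freedom.  With zero variance on both sides: p = 1 for equal
    means, else a p = 0 sentinel with a warning.
    """
    a = np.asarray(control_reps, dtype=float)
    b = np.asarray(exp_reps, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per side")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    n1, n2 = len(a), len(b)
    if v1 == 0 and v2 == 0:
        if a.mean() == b.mean():
            return 0.0, float(n1 + n2 - 2), 1.0
        warnings.warn("zero variance with unequal means: p = 0 sentinel")
        return math.inf, float(n1 + n2 - 2), 0.0
    se2 = v1 / n1 + v2 / n2
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample *a* vs *b* using midranks for ties."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(a)].sum()
    return float(r1 - len(a) * (len(a) + 1) / 2.0)


def pvalues_mannwhitney(control_reps: np.ndarray, exp_reps: np.ndarray,
                        exact_max_n: int = 20) -> tuple[float, float]:
    """Mann-Whitney U test: (U, two-sided p).

    Exact p by full enumeration of group assignments when the pooled sample
    size is <= ``exact_max_n`` (ties handled by enumerating the observed
    value vector with midranks); otherwise the normal approximation on U
    with tie-corrected variance.  Exact two-sided p = 2 * min(tail
    probabilities), clamped to 1.
    """
    a = np.asarray(control_reps, dtype=float)
    b = np.asarray(exp_reps, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("need >= 1 observation per side")
    n1, n2 = len(a), len(b)
    u_obs = _u_statistic(a, b)

    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)          # midranks; reused per assignment
        idx = range(n1 + n2)
        us = []
        offset = n1 * (n1 + 1) / 2.0
        for comb in combinations(idx, n1):
            us.append(ranks[list(comb)].sum() - offset)
        us = np.asarray(us)
        lo = float((us <= u_obs + 1e-12).mean())
        hi = float((us >= u_obs - 1e-12).mean())
        p = min(1.0, 2.0 * min(lo, hi))
        return u_obs, p

    pooled = np.concatenate([a, b])
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return u_obs, 1.0
    z = (u_obs - mu) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return u_obs, float(p)


def bonferroni(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Bonferroni adjustment min(1, p*m) for m tested strains."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m) if np.ndim(p) \
        else min(1.0, float(p) * m)


def shimazaki_bin_width(data: np.ndarray, n_candidates: int = 64) -> float:
    """Histogram bin width minimizing the Shimazaki-Shinomoto cost.

    C(delta) = (2*kbar - v) / delta^2, where kbar and v are the mean and
    biased variance of the per-bin counts.  The width is searched over
    ``n_candidates`` log-spaced values between range/200 and range/2; ties
    resolve to the smallest width.
    """
    x = np.asarray(data, dtype=float)
    x = x[np.isfinite(x)]
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct values")
    span = x.max() - x.min()
    widths = np.geomspace(span / 200.0, span / 2.0, n_candidates)
    best_w, best_c = widths[0], math.inf
    for w in widths:
        nbins = max(1, int(np.ceil(span / w)))
        counts, _ = np.histogram(x, bins=nbins, range=(x.min(), x.min() + nbins * w))
        kbar = counts.mean()
        v = counts.var()          # biased
        c = (2.0 * kbar - v) / (w * w)
        if c < best_c:
            best_c, best_w = c, w
    return float(best_w)


# ---------------------------------------------------------------------------
# full pipeline


def _apply_manual(excl: np.ndarray, manual: pd.DataFrame,
                  plate: str, cond: str) -> np.ndarray:
    sel = manual[(manual["plate"].astype(str) == plate)
                 & (manual["condition"].astype(str) == cond)]
    for _, row in sel.iterrows():
        r, c = int(row["row"]) - 1, int(row["col"]) - 1
        excl[r, c] = bool(int(row["flag"]))
    return excl


def review_pipeline(
    table: MeasurementTable,
    key: PlateKey,
    fmt: GridFormat,
    norm_config: NormalizationConfig | None = None,
    excl_params: ExclusionParams | None = None,
    stat_config: StatConfig | None = None,
    manual_exclusions: pd.DataFrame | None = None,
    control_condition: str = "control",
) -> ReviewedDataset:
    """Normalize -> flag -> exclude -> test -> classify, deterministically.

    Plates pair by plate id: the ``control_condition`` plate is the comparer
    for every other condition with the same id.  Manual exclusions (columns
    ``plate, condition, row, col, flag``) override the automatic masks last.
    Raises :class:`PairingError` when a condition lacks its comparer.
    """
    norm_config = norm_config or NormalizationConfig()
    excl_params = excl_params or ExclusionParams()
    stat_config = stat_config or StatConfig()

    annotated = join_key(table, key)
    normed = normalize(annotated, norm_config, key)
    df = normed.data.copy()

    # masks per physical plate
    df["low_growth"] = False
    df["excluded"] = False
    for (plate, cond), grp in df.groupby(["plate", "condition"], sort=False):
        grid = plate_grid(grp, fmt)
        med = np.nanmedian(grid)
        pm_units = grid / med if med > 0 else grid
        low = np.nan_to_num(pm_units, nan=np.inf) < excl_params.low_growth_fraction
        excl = np.zeros(fmt.shape, dtype=bool)
        if excl_params.enable_global:
            excl |= exclude_global(pm_units, excl_params)
        if excl_params.enable_replicate and fmt.replicate_layout == "quad_2x2":
            excl |= exclude_replicates(pm_units, fmt, excl_params)
        if manual_exclusions is not None and len(manual_exclusions):
            excl = _apply_manual(excl, manual_exclusions, str(plate), str(cond))
        ridx = grp["row"].to_numpy() - 1
        cidx = grp["col"].to_numpy() - 1
        df.loc[grp.index, "low_growth"] = low[ridx, cidx]
        df.loc[grp.index, "excluded"] = excl[ridx, cidx]

    # pairing
    conds = df["condition"].unique().tolist()
    if control_condition not in conds:
        raise PairingError(f"no {control_condition!r} condition in data")
    exp_conds = [c for c in conds if c != control_condition]
    if not exp_conds:
        raise PairingError("no experimental condition to compare against")
    ctrl_plates = set(df.loc[df["condition"] == control_condition, "plate"])
    orphans = [
        (p, c) for c in exp_conds
        for p in set(df.loc[df["condition"] == c, "plate"]) - ctrl_plates
    ]
    if orphans:
        raise PairingError(f"experimental plates without comparer: {orphans}")

    all_stats = []
    for cond in exp_conds:
        for plate in sorted(set(df.loc[df["condition"] == cond, "plate"])):
            c_df = df[(df["plate"] == plate) & (df["condition"] == control_condition)]
            e_df = df[(df["plate"] == plate) & (df["condition"] == cond)]
            st = strain_ratios(c_df, e_df, stat_config.log_base)
            st["condition"] = cond
            all_stats.append(st)
    stats = pd.concat(all_stats, ignore_index=True)

    # statistics
    stats["z_score"] = np.nan
    stats["p_value"] = np.nan
    if stat_config.test == "normal_distribution":
        z, p = pvalues_normal(stats["log_ratio"].to_numpy(),
                              stat_config.population_sd)
        stats["z_score"] = z
        stats["p_value"] = p
    else:
        # per-strain replicate vectors (non-excluded values)
        kept = df[~df["excluded"]]
        for i, row in stats.iterrows():
            sel = (kept["strain"] == row["strain"]) & (kept["plate"] == row["plate"])
            a = kept.loc[sel & (kept["condition"] == control_condition),
                         "value"].to_numpy()
            b = kept.loc[sel & (kept["condition"] == row["condition"]),
                         "value"].to_numpy()
            try:
                if stat_config.test == "welch_t":
                    t, _, p = pvalues_welch(a, b)
                    stats.loc[i, "z_score"] = t
                else:
                    u, p = pvalues_mannwhitney(a, b)
                    stats.loc[i, "z_score"] = u
                stats.loc[i, "p_value"] = p
            except ValueError:
                continue      # too few replicates: flagged, not tested

    if stat_config.bonferroni:
        m = int(stats["p_value"].notna().sum())
        stats["p_adjusted"] = bonferroni(stats["p_value"].to_numpy(), max(m, 1))
    else:
        stats["p_adjusted"] = stats["p_value"]

    cols = [c for c in STATS_COLUMNS if c in stats.columns]
    stats = stats[cols + [c for c in stats.columns if c not in cols]]
    return ReviewedDataset(df, stats, norm_config, excl_params, stat_config)
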