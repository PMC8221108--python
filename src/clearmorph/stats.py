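"""Sample summaries, paired ratios, histograms and group comparisons.

Cell counts are normalized by tissue volume (reported per 10⁶ µm³ of
tissue, i.e. per 0.001 mm³) so that samples of different physical size
are comparable.  Ipsilateral/contralateral ratios within one animal and
tissue control for the resident baseline population.  Group comparisons
follow the conventional design for this kind of cohort: Welch two-sample
t-tests for single comparisons and one-/two-way ANOVA with
Bonferroni-adjusted pairwise contrasts for multi-group designs, at
α = 0.05.  The Bonferroni family is defined as all pairwise contrasts
within one ANOVA.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .io import SampleMetadata
from .morphometry import MorphometryRecord

__all__ = [
    "SampleSummary",
    "PairedRatio",
    "Contrast",
    "GroupComparison",
    "InsufficientDataError",
    "summarize_sample",
    "ipsi_contra_ratio",
    "volume_frequency_distribution",
    "compare_groups",
    "shape_scatter_table",
]

DENSITY_SCALE = 1e6  # report cells per 10^6 µm³ of tissue


class InsufficientDataError(ValueError):
    """A design cell has fewer than the minimum observations; names the cell."""


@dataclass
class SampleSummary:
    """Per-sample aggregate of the morphometry table."""

    metadata: SampleMetadata
    n_cells: int
    tissue_volume_um3: float
    density_per_1e6um3: float
    mean_cell_volume_um3: float
    mean_sphericity: float
    mean_e_prolate: float
    mean_e_oblate: float
    histogram_edges_um3: np.ndarray
    histogram_freq: np.ndarray
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.metadata.to_dict()
        d.update(
            n_cells=self.n_cells,
            tissue_volume_um3=self.tissue_volume_um3,
            density_per_1e6um3=self.density_per_1e6um3,
            mean_cell_volume_um3=self.mean_cell_volume_um3,
            mean_sphericity=self.mean_sphericity,
            mean_e_prolate=self.mean_e_prolate,
            mean_e_oblate=self.mean_e_oblate,
            flags=";".join(self.flags),
        )
        return d


@dataclass
class PairedRatio:
    """Ipsilateral / contralateral ratio for one animal and tissue."""

    animal_id: str
    tissue: str
    count_ratio: float  # nan when contra count is 0 (flagged)
    mean_volume_ratio: float
    flags: list[str] = field(default_factory=list)


@dataclass
class Contrast:
    """One pairwise comparison inside a Bonferroni family."""

    groups: tuple[str, str]
    statistic: float
    p_raw: float
    p_adj: float
    significant: bool


@dataclass
class GroupComparison:
    """Result of one statistical test over a factor design."""

    factors: tuple[str, ...]
    test: str  # t_test | anova_1way | anova_2way
    statistic: float
    p_value: float
    alpha: float
    contrasts: list[Contrast] = field(default_factory=list)
    term: str = ""

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.to_dict() for r in records])


def summarize_sample(
    records,
    tissue_volume_um3: float,
    metadata: SampleMetadata,
    histogram_bins: np.ndarray | int = 20,
    histogram_range: tuple[float, float] | None = None,
) -> SampleSummary:
    """Aggregate one sample's morphometry records.

    ``density = n_cells / tissue_volume × 10⁶`` exactly.  An empty record
    set is valid: count 0, empty histogram, undefined means flagged.
    """
    if tissue_volume_um3 <= 0:
        raise ValueError(f"tissue volume must be positive; got {tissue_volume_um3}")
    df = _records_frame(records)
    n = len(df)
    flags: list[str] = []
    if n == 0:
        return SampleSummary(
            metadata=metadata,
            n_cells=0,
            tissue_volume_um3=float(tissue_volume_um3),
            density_per_1e6um3=0.0,
            mean_cell_volume_um3=np.nan,
            mean_sphericity=np.nan,
            mean_e_prolate=np.nan,
            mean_e_oblate=np.nan,
            histogram_edges_um3=np.array([]),
            histogram_freq=np.array([]),
            flags=["no_cells"],
        )
    volumes = df["volume_um3"].to_numpy(dtype=float)
    if isinstance(histogram_bins, (int, np.integer)):
        edges = np.histogram_bin_edges(volumes, bins=histogram_bins, range=histogram_range)
    else:
        edges = np.asarray(histogram_bins, dtype=float)
    hist, edges = np.histogram(volumes, bins=edges)
    freq = hist / hist.sum() if hist.sum() else hist.astype(float)
    return SampleSummary(
        metadata=metadata,
        n_cells=n,
        tissue_volume_um3=float(tissue_volume_um3),
        density_per_1e6um3=n / tissue_volume_um3 * DENSITY_SCALE,
        mean_cell_volume_um3=float(np.mean(volumes)),
        mean_sphericity=float(np.nanmean(df["sphericity"].to_numpy(dtype=float))),
        mean_e_prolate=float(np.nanmean(df["e_prolate"].to_numpy(dtype=float))),
        mean_e_oblate=float(np.nanmean(df["e_oblate"].to_numpy(dtype=float))),
        histogram_edges_um3=edges,
        histogram_freq=freq,
        flags=flags,
    )


def ipsi_contra_ratio(ipsi: SampleSummary, contra: SampleSummary) -> PairedRatio:
    """Injured-over-uninjured side ratios for one animal and tissue.

    A zero contralateral count (or undefined mean volume) yields a
    flagged ``nan`` ratio, never an infinity.
    """
    mi, mc = ipsi.metadata, contra.metadata
    if (mi.animal_id, mi.tissue) != (mc.animal_id, mc.tissue):
        raise ValueError(
            f"paired samples must share animal and tissue; got "
            f"{(mi.animal_id, mi.tissue)} vs {(mc.animal_id, mc.tissue)}"
        )
    if (mi.side, mc.side) != ("ipsilateral", "contralateral"):
        raise ValueError(f"expected (ipsilateral, contralateral); got ({mi.side}, {mc.side})")
    flags: list[str] = []
    if contra.n_cells == 0:
        count_ratio = np.nan
        flags.append("contra_zero_count")
    else:
        count_ratio = ipsi.n_cells / contra.n_cells
    if contra.n_cells == 0 or ipsi.n_cells == 0 or not np.isfinite(contra.mean_cell_volume_um3):
        mean_volume_ratio = np.nan
        if "contra_zero_count" not in flags:
            flags.append("undefined_volume_ratio")
    else:
        mean_volume_ratio = ipsi.mean_cell_volume_um3 / contra.mean_cell_volume_um3
    return PairedRatio(
        animal_id=mi.animal_id,
        tissue=mi.tissue,
        count_ratio=float(count_ratio),
        mean_volume_ratio=float(mean_volume_ratio),
        flags=flags,
    )


def volume_frequency_distribution(
    groups: dict[str, "pd.DataFrame | list[MorphometryRecord]"],
    bins: int | np.ndarray = 20,
) -> pd.DataFrame:
    """Relative cell-volume frequency per bin per group, shared bin edges.

    Bin edges span the pooled volume range so groups are directly
    comparable; each non-empty group's frequencies sum to 1.  Empty
    groups get an all-zero row flagged in the ``empty`` column.
    """
    frames = {k: _records_frame(v) for k, v in groups.items()}
    pooled = np.concatenate(
        [f["volume_um3"].to_numpy(dtype=float) for f in frames.values() if len(f)]
        or [np.array([0.0, 1.0])]
    )
    if isinstance(bins, (int, np.integer)):
        edges = np.histogram_bin_edges(pooled, bins=bins)
    else:
        edges = np.asarray(bins, dtype=float)
    rows = []
    for name, f in frames.items():
        if len(f):
            hist, _ = np.histogram(f["volume_um3"].to_numpy(dtype=float), bins=edges)
            freq = hist / hist.sum()
            empty = False
        else:
            freq = np.zeros(len(edges) - 1)
            empty = True
        for i, fr in enumerate(freq):
            rows.append(
                {
                    "group": name,
                    "bin_left_um3": edges[i],
                    "bin_right_um3": edges[i + 1],
                    "frequency": fr,
                    "empty": empty,
                }
            )
    return pd.DataFrame(rows)


def _ttest(xa: np.ndarray, xb: np.ndarray, equal_var: bool) -> tuple[float, float]:
    """Two-sample t-test robust to the zero-variance degenerate case."""
    if np.var(xa) == 0 and np.var(xb) == 0:
        # no within-group variability: identical means are maximally
        # non-significant, different means trivially significant
        return (0.0, 1.0) if np.mean(xa) == np.mean(xb) else (np.inf, 0.0)
    t, p = sps.ttest_ind(xa, xb, equal_var=equal_var)
    return float(t), float(p)


def _check_cells(obs: pd.DataFrame, factors: list[str], min_n: int = 2) -> None:
    for key, group in obs.groupby(list(factors)):
        if len(group) < min_n:
            raise InsufficientDataError(
                f"design cell {dict(zip(factors, np.atleast_1d(key)))} has "
                f"{len(group)} observation(s); need ≥ {min_n}"
            )


def compare_groups(
    obs: pd.DataFrame,
    value: str,
    factors: list[str] | str,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> list[GroupComparison]:
    """Run the test appropriate to the factor design.

    One factor, two levels → two-sample t-test (Welch by default; set
    ``equal_var=True`` for the pooled-variance form).  One factor, more
    levels → one-way ANOVA.  Two factors → two-way ANOVA with
    interaction.  ANOVAs are followed by all pairwise (cell-wise)
    t-contrasts with Bonferroni adjustment; that family is the set of
    contrasts reported.

    ``obs`` holds one row per observation (typically one per sample)
    with factor columns and a numeric ``value`` column.
    """
    if isinstance(factors, str):
        factors = [factors]
    if not 1 <= len(factors) <= 2:
        raise ValueError("one or two factors supported")
    obs = obs.dropna(subset=[value])
    _check_cells(obs, factors)

    cell_labels = obs[factors].astype(str).agg(":".join, axis=1)
    cells = {name: obs.loc[cell_labels == name, value].to_numpy(dtype=float)
             for name in sorted(cell_labels.unique())}
    if len(cells) < 2:
        raise InsufficientDataError(
            f"need at least two groups to compare; got {sorted(cells)}"
        )

    def pairwise(n_family: int) -> list[Contrast]:
        out = []
        for (na, xa), (nb, xb) in itertools.combinations(cells.items(), 2):
            t, p = _ttest(xa, xb, equal_var)
            p_adj = min(1.0, p * n_family)
            out.append(
                Contrast(
                    groups=(na, nb),
                    statistic=float(t),
                    p_raw=float(p),
                    p_adj=p_adj,
                    significant=bool(p_adj < alpha),
                )
            )
        return out

    results: list[GroupComparison] = []
    if len(factors) == 1 and len(cells) == 2:
        (xa, xb) = cells.values()
        t, p = _ttest(xa, xb, equal_var)
        contrast = Contrast(
            groups=tuple(cells.keys()),  # type: ignore[arg-type]
            statistic=float(t),
            p_raw=float(p),
            p_adj=float(p),
            significant=bool(p < alpha),
        )
        results.append(
            GroupComparison(
                factors=tuple(factors),
                test="t_test",
                statistic=float(t),
                p_value=float(p),
                alpha=alpha,
                contrasts=[contrast],
            )
        )
        return results

    n_family = len(cells) * (len(cells) - 1) // 2
    if len(factors) == 1:
        f, p = sps.f_oneway(*cells.values())
        results.append(
            GroupComparison(
                factors=tuple(factors),
                test="anova_1way",
                statistic=float(f),
                p_value=float(p),
                alpha=alpha,
                contrasts=pairwise(n_family),
                term=factors[0],
            )
        )
        return results

    # two-way ANOVA with interaction via OLS
    data = obs[[value] + factors].copy()
    data.columns = ["value", "f1", "f2"]
    model = ols("value ~ C(f1) * C(f2)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    contrasts = pairwise(n_family)
    for term in ["C(f1)", "C(f2)", "C(f1):C(f2)"]:
        pretty = (
            term.replace("C(f1)", factors[0]).replace("C(f2)", factors[1])
        )
        results.append(
            GroupComparison(
                factors=tuple(factors),
                test="anova_2way",
                statistic=float(table.loc[term, "F"]),
                p_value=float(table.loc[term, "PR(>F)"]),
                alpha=alpha,
                contrasts=contrasts,
                term=pretty,
            )
        )
    return results


def shape_scatter_table(groups: dict[str, "pd.DataFrame | list[MorphometryRecord]"]) -> pd.DataFrame:
    """Tidy long table of (e_oblate, e_prolate, sphericity) per cell per group.

    One row per cell — the data behind an oblateness-vs-prolateness
    scatter colored by group.
    """
    rows = []
    for name, recs in groups.items():
        f = _records_frame(recs)
        if len(f) == 0:
            continue
        for _, r in f.iterrows():
            rows.append(
                {
                    "group": name,
                    "e_oblate": r["e_oblate"],
                    "e_prolate": r["e_prolate"],
                    "sphericity": r["sphericity"],
                }
            )
    return pd.DataFrame(rows, columns=["group", "e_oblate", "e_prolate", "sphericity"])
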