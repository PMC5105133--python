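"""Group statistics on divisional coherence values.

For each electrode pair and each band x period area, per-trial divisional
WC values are pooled across subjects by group and compared with a
pooled-variance two-sample t-test (trials are the sampling unit, so with
1560 trials per group df = 3118).  Within each area the 66 pair-wise
p-values form one multiplicity family corrected by Benjamini-Hochberg FDR.
A pair is "significant" in an area when the corrected p is strictly below
the level (default 0.05).

The selection algebra:  M1 and M3 are the 12x12 binary significance
matrices of the pre-stimulus (1#) and P300-processing (3#) periods;
L = (NOT M1) AND M3 marks pairs that differ during deception processing
but not at rest -- the "selected lying connections".  Delta1/Delta3 are
the guilty-minus-innocent mean WC differences per pair in the two periods;
Delta3 later weights the network edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .grids import BAND_ORDER
from .montage import CHANNELS

logger = logging.getLogger(__name__)


def pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Student's pooled-variance two-sample t-test: (t, two-sided p, df).

    Degenerate zero-variance input follows the convention p = 0 when the
    means differ (infinitely strong evidence) and p = 1 when they agree.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    df = len(a) + len(b) - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, df
        logger.warning("zero pooled variance with unequal means; p set to 0")
        return float(np.inf if a.mean() > b.mean() else -np.inf), 0.0, df
    t, p = sp_stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), df


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (corrected p-values, rejection mask).

    The mask follows the step-up rule on the raw p-values (reject the
    smallest k with ``p_(i) <= i q / m`` for all i <= k), which for
    continuous p-values coincides with ``corrected p < q``; the step-up
    form also handles the exact-boundary case ``p_(i) = i q / m``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_corr, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_corr, reject


@dataclass
class StatMatrixSet:
    """Per-band significance matrices and the full per-pair test table."""

    band: str
    M1: np.ndarray  # 12x12 binary symmetric, zero diagonal
    M3: np.ndarray
    L: np.ndarray  # (NOT M1) AND M3
    tests: pd.DataFrame  # pair, period, t, p_raw, p_fdr, df, delta
    channels: tuple[str, ...] = CHANNELS

    def selected_pairs(self) -> list[tuple[str, str]]:
        """Upper-triangle 1s of L in canonical pair order."""
        out = []
        for i in range(len(self.channels)):
            for j in range(i + 1, len(self.channels)):
                if self.L[i, j]:
                    out.append((self.channels[i], self.channels[j]))
        return out


@dataclass
class DeltaTable:
    """Guilty-minus-innocent mean WC per pair for periods 1# and 3#."""

    band: str
    table: pd.DataFrame  # pair, delta1, delta3


def group_delta(
    divisional: pd.DataFrame, pair: str, band: str, period: str
) -> float:
    """Mean guilty WC minus mean innocent WC for one pair/band/period."""
    cell = divisional[
        (divisional["pair"] == pair)
        & (divisional["band"] == band)
        & (divisional["period"] == period)
    ]
    g = cell.loc[cell["group"] == "guilty", "wc"]
    i = cell.loc[cell["group"] == "innocent", "wc"]
    if len(g) == 0 or len(i) == 0:
        raise ValueError(f"both groups required for {pair}/{band}/{period}")
    return float(g.mean() - i.mean())


def raw_area_tests(
    divisional: pd.DataFrame, band: str, period: str
) -> pd.DataFrame:
    """Pooled t-tests for all pairs of one band x period area, uncorrected."""
    sub = divisional[(divisional["band"] == band) & (divisional["period"] == period)]
    rows = []
    for pair_label, cell in sub.groupby("pair", sort=False):
        g = cell.loc[cell["group"] == "guilty", "wc"].to_numpy()
        i = cell.loc[cell["group"] == "innocent", "wc"].to_numpy()
        t, p, df = pooled_ttest(g, i)
        rows.append(
            {
                "pair": pair_label,
                "band": band,
                "period": period,
                "t": t,
                "p_raw": p,
                "df": df,
                "delta": float(g.mean() - i.mean()),
            }
        )
    return pd.DataFrame(rows)


def area_tests(
    divisional: pd.DataFrame, band: str, period: str, q: float = 0.05
) -> pd.DataFrame:
    """Pooled t-tests for all pairs in one band x period area, FDR-corrected.

    The 66 pairs of the area form one BH family (the per-area default;
    ``all_band_statistics`` exposes a global family).
    """
    out = raw_area_tests(divisional, band, period)
    p_corr, reject = bh_fdr(out["p_raw"].to_numpy(), q)
    out["p_fdr"] = p_corr
    out["significant"] = reject
    return out


def build_stat_matrix(
    divisional: pd.DataFrame,
    band: str,
    period: str,
    q: float = 0.05,
    channels: tuple[str, ...] = CHANNELS,
) -> tuple[np.ndarray, pd.DataFrame]:
    """12x12 binary significance matrix for one area (symmetric, zero diag)."""
    tests = area_tests(divisional, band, period, q)
    return _matrix_from_tests(tests, channels), tests


def select_lying_connections(
    M1: np.ndarray, M3: np.ndarray, channels: tuple[str, ...] = CHANNELS
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """L = (NOT M1) AND M3, plus its upper-triangle pair list.

    A pair qualifies when it is significant during the P300-processing
    period and not during the pre-stimulus period.
    """
    M1 = np.asarray(M1)
    M3 = np.asarray(M3)
    if M1.shape != M3.shape:
        raise ValueError("M1 and M3 must have the same shape")
    L = ((1 - M1) & M3).astype(int)
    np.fill_diagonal(L, 0)
    pairs = [
        (channels[i], channels[j])
        for i in range(len(channels))
        for j in range(i + 1, len(channels))
        if L[i, j]
    ]
    return L, pairs


def compute_band_statistics(
    divisional: pd.DataFrame,
    band: str,
    q: float = 0.05,
    channels: tuple[str, ...] = CHANNELS,
) -> tuple[StatMatrixSet, DeltaTable]:
    """Full selection algebra for one band: M1, M3, L and Delta1/Delta3."""
    M1, tests1 = build_stat_matrix(divisional, band, "1#", q, channels)
    M3, tests3 = build_stat_matrix(divisional, band, "3#", q, channels)
    L, _ = select_lying_connections(M1, M3, channels)
    tests = pd.concat([tests1, tests3], ignore_index=True)
    deltas = pd.DataFrame(
        {
            "pair": tests1["pair"],
            "delta1": tests1["delta"].to_numpy(),
            "delta3": tests3.set_index("pair").loc[tests1["pair"], "delta"].to_numpy(),
        }
    )
    return (
        StatMatrixSet(band=band, M1=M1, M3=M3, L=L, tests=tests, channels=channels),
        DeltaTable(band=band, table=deltas),
    )


def _matrix_from_tests(tests: pd.DataFrame, channels) -> np.ndarray:
    n = len(channels)
    M = np.zeros((n, n), dtype=int)
    for _, row in tests[tests["significant"]].iterrows():
        a, b = row["pair"].split("-")
        i, j = channels.index(a), channels.index(b)
        M[i, j] = M[j, i] = 1
    return M


def all_band_statistics(
    divisional: pd.DataFrame,
    q: float = 0.05,
    family: str = "per-area",
    channels: tuple[str, ...] = CHANNELS,
) -> dict[str, tuple[StatMatrixSet, DeltaTable]]:
    """Selection algebra for every band present in the table.

    ``family`` chooses the FDR multiplicity family: ``"per-area"``
    (66 pairs within one band x period, the default) or ``"global"``
    (all pairs of all analysed 1#/3# areas jointly -- more conservative
    for concentrated effects).
    """
    bands = [b for b in BAND_ORDER if b in set(divisional["band"])]
    if family == "per-area":
        return {b: compute_band_statistics(divisional, b, q, channels) for b in bands}
    if family != "global":
        raise ValueError(f"unknown FDR family {family!r}")
    raw = pd.concat(
        [raw_area_tests(divisional, b, p) for b in bands for p in ("1#", "3#")],
        ignore_index=True,
    )
    p_corr, reject = bh_fdr(raw["p_raw"].to_numpy(), q)
    raw["p_fdr"] = p_corr
    raw["significant"] = reject
    out = {}
    for b in bands:
        t1 = raw[(raw["band"] == b) & (raw["period"] == "1#")].reset_index(drop=True)
        t3 = raw[(raw["band"] == b) & (raw["period"] == "3#")].reset_index(drop=True)
        M1 = _matrix_from_tests(t1, channels)
        M3 = _matrix_from_tests(t3, channels)
        L, _ = select_lying_connections(M1, M3, channels)
        deltas = pd.DataFrame(
            {
                "pair": t1["pair"],
                "delta1": t1["delta"].to_numpy(),
                "delta3": t3.set_index("pair").loc[t1["pair"], "delta"].to_numpy(),
            }
        )
        out[b] = (
            StatMatrixSet(
                band=b, M1=M1, M3=M3, L=L,
                tests=pd.concat([t1, t3], ignore_index=True),
                channels=channels,
            ),
            DeltaTable(band=b, table=deltas),
        )
    return out


def matrix_to_frame(M: np.ndarray, channels: tuple[str, ...] = CHANNELS) -> pd.DataFrame:
    """Labelled DataFrame view of a 12x12 matrix for text export."""
    return pd.DataFrame(M, index=list(channels), columns=list(channels))
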