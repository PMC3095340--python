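"""Audic-Claverie differential-expression testing between two libraries.

For a tag observed ``x`` times among ``N1`` tags in one library and ``y``
times among ``N2`` tags in the other, the Audic-Claverie model treats the
counts as Poisson samples of a common underlying expression level and
evaluates the conditional probability of the second count given the
first::

    p(y | x) = (N2/N1)^y * (x + y)! / (x! * y! * (1 + N2/N1)^(x + y + 1))

which is a negative-binomial mass in ``y`` with ``x + 1`` "successes" and
success probability ``1 / (1 + N2/N1)``. All factorial terms are computed
through log-gamma, so arbitrarily deep libraries do not overflow. The
two-sided p-value doubles the smaller of the two cumulative tails at the
observed ``y`` (capped at 1); a one-sided alternative is available.

Fold change is computed on the normalized-to-100,000 scale as F/W with
zero counts replaced by 1 before division, and a tag is called
differentially expressed when its p-value passes ``alpha`` *and* its fold
change passes the up or down threshold. Singletons (combined count 1)
are excluded from testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

_TINY_P = 1e-300  # p-values are clamped into (0, 1]
_TAIL_RESIDUAL = 1e-12  # stop upper-tail summation at this relative residual


@dataclass(frozen=True)
class Thresholds:
    """Significance and fold-change thresholds for calling and selection."""

    alpha: float = 0.05
    fc_up: float = 2.5
    fc_down: float = 0.4
    abundance_cap: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.fc_down < 1 < self.fc_up:
            raise ValueError("need fc_down < 1 < fc_up")
        if self.abundance_cap <= 0:
            raise ValueError("abundance_cap must be positive")


def _check_counts(x, y, N1, N2) -> tuple[int, int]:
    for name, value in (("x", x), ("y", y)):
        if value != int(value) or value < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {value}")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals N1, N2 must be positive")
    return int(x), int(y)


def log_ac_probability(x: int, ys, N1: float, N2: float):
    """log p(y | x) for one x and a vector of y values."""
    r = N2 / N1
    ys = np.asarray(ys, dtype=float)
    return (
        ys * np.log(r)
        + gammaln(x + ys + 1)
        - gammaln(x + 1)
        - gammaln(ys + 1)
        - (x + ys + 1) * np.log1p(r)
    )


def ac_probability(x: int, y: int, N1: float, N2: float) -> float:
    """Audic-Claverie probability mass p(y | x)."""
    x, y = _check_counts(x, y, N1, N2)
    return float(np.exp(log_ac_probability(x, np.array([y]), N1, N2)[0]))


def _upper_tail(x: int, y: int, N1: float, N2: float) -> float:
    """P(Y >= y | x) by direct summation of decreasing terms.

    Only called when the upper tail is the minor one (y at or beyond the
    bulk of the distribution), where successive term ratios fall below 1
    and the remaining mass is bounded by a geometric series; summation
    stops once that bound drops below ``_TAIL_RESIDUAL`` of the
    accumulated sum.
    """
    r = N2 / N1
    q = r / (1.0 + r)
    term = float(np.exp(log_ac_probability(x, np.array([y]), N1, N2)[0]))
    total = term
    k = y
    while True:
        ratio = q * (x + k + 1) / (k + 1)
        if ratio < 1.0:
            bound = term * ratio / (1.0 - ratio)
            if bound < _TAIL_RESIDUAL * total:
                return total
        term *= ratio
        k += 1
        total += term
        if k > y + 10_000_000:  # pragma: no cover - safety stop
            return total


def ac_pvalue(
    x: int, y: int, N1: float, N2: float, sided: str = "two-sided"
) -> float:
    """Audic-Claverie p-value for a tag counted ``x``/``N1`` vs ``y``/``N2``.

    ``sided`` is ``"two-sided"`` (default: twice the smaller tail, capped
    at 1), ``"less"`` (P(Y <= y | x)) or ``"greater"`` (P(Y >= y | x)).
    """
    x, y = _check_counts(x, y, N1, N2)
    lower_log = logsumexp(log_ac_probability(x, np.arange(y + 1), N1, N2))
    lower = float(np.exp(lower_log))
    if y == 0:
        upper = 1.0
    elif lower - ac_probability(x, y, N1, N2) <= 0.5:
        # lower tail below y holds at most half the mass: its complement
        # (the upper tail) is large and accurate through 1 - P(Y <= y-1)
        below_log = logsumexp(log_ac_probability(x, np.arange(y), N1, N2))
        upper = 1.0 - float(np.exp(below_log))
    else:
        upper = _upper_tail(x, y, N1, N2)
    if sided == "less":
        p = lower
    elif sided == "greater":
        p = upper
    elif sided == "two-sided":
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return float(min(1.0, max(p, _TINY_P)))


def fold_change(norm100k_F, norm100k_W):
    """Fold change F vs W on the per-100,000 scale, zero counts set to 1.

    Scalar in, scalar out; array-like in, numpy array out.
    """
    f = np.asarray(norm100k_F, dtype=float)
    w = np.asarray(norm100k_W, dtype=float)
    if (f < 0).any() or (w < 0).any():
        raise ValueError("normalized counts must be >= 0")
    f = np.where(f == 0, 1.0, f)
    w = np.where(w == 0, 1.0, w)
    out = f / w
    if np.isscalar(norm100k_F) and np.isscalar(norm100k_W):
        return float(out[()])
    return out


def classify_de(
    p_value: float, fc: float, thresholds: Thresholds = Thresholds()
) -> tuple[str, bool]:
    """Direction and significance for one tested tag.

    Returns ``(direction, significant)`` where direction is ``up`` when
    significant and fc >= fc_up, ``down`` when significant and
    fc <= fc_down, else ``unchanged``.
    """
    significant = p_value <= thresholds.alpha
    if significant and fc >= thresholds.fc_up:
        direction = "up"
    elif significant and fc <= thresholds.fc_down:
        direction = "down"
    else:
        direction = "unchanged"
    return direction, significant


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (step-up, monotone)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def de_test(
    table: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    sided: str = "two-sided",
    bh: bool = False,
) -> pd.DataFrame:
    """Run the Audic-Claverie test on every UniTag of a count table.

    ``table`` is a normalized, status-classified count table (index tag,
    columns ``raw_W, raw_F, norm100k_W, norm100k_F, status``). Singletons
    are excluded. With ``bh=True`` a Benjamini-Hochberg ``q_value``
    column is added and significance uses q <= alpha instead of the raw
    p-value (off by default: the original analysis applied a raw 95%
    confidence level).
    """
    if "status" not in table.columns:
        raise ValueError("table must carry UniTag/singleton status")
    unitags = table[table["status"] == "unitag"]
    n1 = int(table["raw_W"].sum())
    n2 = int(table["raw_F"].sum())
    x = unitags["raw_W"].to_numpy()
    y = unitags["raw_F"].to_numpy()
    p_values = np.array(
        [ac_pvalue(xi, yi, n1, n2, sided=sided) for xi, yi in zip(x, y)]
    )
    fc = fold_change(unitags["norm100k_F"].to_numpy(), unitags["norm100k_W"].to_numpy())
    results = pd.DataFrame(
        {
            "tag": unitags.index,
            "x": x,
            "y": y,
            "N1": n1,
            "N2": n2,
            "p_value": p_values,
            "fc": fc,
        }
    )
    effective_p = p_values
    if bh:
        results["q_value"] = benjamini_hochberg(p_values)
        effective_p = results["q_value"].to_numpy()
    significant = effective_p <= thresholds.alpha
    direction = np.where(
        significant & (fc >= thresholds.fc_up),
        "up",
        np.where(significant & (fc <= thresholds.fc_down), "down", "unchanged"),
    )
    results["direction"] = direction
    results["significant"] = significant
    return results.reset_index(drop=True)


def volcano_table(results: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Per-tag volcano/abundance coordinates.

    Columns: ``log2_fc``, ``neg_log10_p`` and ``cpm`` (mean of the two
    libraries' copies-per-million; the abundance axis of the
    fold-change-vs-abundance view). All coordinates are finite because
    fc > 0 and p > 0 are guaranteed upstream.
    """
    cpm = (
        table.loc[results["tag"], ["norm_W", "norm_F"]].mean(axis=1).to_numpy()
    )
    return pd.DataFrame(
        {
            "tag": results["tag"],
            "log2_fc": np.log2(results["fc"].to_numpy()),
            "neg_log10_p": -np.log10(results["p_value"].to_numpy()),
            "cpm": cpm,
        }
    )


def select_candidates(
    results: pd.DataFrame,
    table: pd.DataFrame,
    regulatory: Mapping[str, bool] | None = None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Flag candidate tags fulfilling at least two of three criteria.

    1. strong, significant fold change (called up or down),
    2. abundance below ``thresholds.abundance_cap`` copies per million in
       both libraries (regulatory components are low-abundant),
    3. annotated as a known regulatory component.

    Tags missing from ``regulatory`` are treated as non-regulatory.
    """
    regulatory = regulatory or {}
    tags = results["tag"]
    strong_fc = results["direction"].isin(["up", "down"]).to_numpy()
    max_cpm = table.loc[tags, ["norm_W", "norm_F"]].max(axis=1).to_numpy()
    low_abundance = max_cpm < thresholds.abundance_cap
    reg_flag = np.array([bool(regulatory.get(t, False)) for t in tags])
    n_criteria = strong_fc.astype(int) + low_abundance.astype(int) + reg_flag.astype(int)
    out = pd.DataFrame(
        {
            "tag": tags,
            "fc": results["fc"],
            "p_value": results["p_value"],
            "direction": results["direction"],
            "strong_fc": strong_fc,
            "low_abundance": low_abundance,
            "regulatory": reg_flag,
            "candidate": n_criteria >= 2,
        }
    )
    return out.reset_index(drop=True)


def write_results(results: pd.DataFrame, path: Union[str, Path]) -> None:
    results.to_csv(path, sep="\t", index=False)
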