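"""Auxiliary evidence: protein-length correlation and expression profiles.

Orthologous proteins between two related genomes should have near-identical
lengths; a through-origin least-squares fit ``y = a*x`` over candidate pairs
summarises this (the slope has the closed form ``a = Σxy / Σx²``).

Expression evidence pairs genes that are similarly regulated across the four
canonical tissues (LE, F&P, S&S, RO).  Values from different platforms carry
platform-specific multiplication factors, applied before a ``log2(1+x)``
transform; similarity is Pearson correlation of the transformed profiles
(Spearman is available as an alternative).  A candidate pair earns the
``'#'`` expression flag only when its correlation clears ``r_min`` and beats
every competitor sharing an endpoint by at least ``margin``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .records import ExpressionProfile

DEFAULT_R_MIN = 0.8
DEFAULT_MARGIN = 0.1

#: per-platform multiplication factor applied to stored values before the log
PLATFORM_SCALES = {"microarray": 100.0, "rnaseq": 1000.0}


@dataclass(frozen=True)
class LengthFit:
    """Through-origin least-squares fit y = a*x over orthologue length pairs."""

    a: float
    n: int
    residual_rms: float


def length_fit(pairs: Sequence[tuple[float, float]]) -> LengthFit:
    """Fit ``y = a*x`` by least squares; ``a = Σxy / Σx²`` in closed form."""
    if not pairs:
        raise ValueError("no length pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("lengths must be positive")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("sum of squares of x is zero")
    a = float(x @ y) / sxx
    resid = y - a * x
    return LengthFit(a=a, n=len(pairs), residual_rms=float(np.sqrt(np.mean(resid**2))))


def expression_correlation(
    profile_a: ExpressionProfile,
    profile_b: ExpressionProfile,
    tissue_map: Mapping[str, str] | None = None,
    platform_scales: Mapping[str, float] | None = None,
    method: str = "pearson",
    log_transform: bool = True,
) -> float | None:
    """Correlation of two expression profiles across shared tissues.

    Tissue labels of profile B are first renamed through ``tissue_map``;
    each profile is multiplied by its platform's scale factor and
    ``log2(1+x)``-transformed (unless ``log_transform=False``) before the
    correlation.  Fewer than 3 shared tissues means the evidence is missing:
    ``None`` is returned.
    """
    scales = dict(PLATFORM_SCALES)
    if platform_scales:
        scales.update(platform_scales)
    tmap = tissue_map or {}
    b_values = {
        tmap.get(t, t): v for t, v in profile_b.as_dict().items()
    }
    shared = [t for t in profile_a.tissues if t in b_values]
    if len(shared) < 3:
        return None
    va = np.array([profile_a.as_dict()[t] for t in shared]) * scales.get(
        profile_a.platform, 1.0
    )
    vb = np.array([b_values[t] for t in shared]) * scales.get(
        profile_b.platform, 1.0
    )
    if log_transform:
        va = np.log2(1.0 + va)
        vb = np.log2(1.0 + vb)
    if np.std(va) == 0 or np.std(vb) == 0:
        return None  # constant profile: correlation undefined
    if method == "pearson":
        r = stats.pearsonr(va, vb).statistic
    elif method == "spearman":
        r = stats.spearmanr(va, vb).statistic
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r)


def assign_by_expression(
    candidate_pairs: Sequence[tuple[str, str]],
    correlations: Mapping[tuple[str, str], float | None],
    r_min: float = DEFAULT_R_MIN,
    margin: float = DEFAULT_MARGIN,
) -> list[tuple[tuple[str, str], bool]]:
    """Greedy correlation-descending matching with conservative flagging.

    Pairs with missing correlation never match.  A matched pair is flagged
    ``'#'`` iff its correlation is at least ``r_min`` and exceeds every
    competing candidate sharing either endpoint by at least ``margin``.
    """
    def corr(p: tuple[str, str]) -> float:
        c = correlations.get(p)
        return -math.inf if c is None else c

    order = sorted(candidate_pairs, key=lambda p: (-corr(p), p))
    used_a: set[str] = set()
    used_b: set[str] = set()
    out: list[tuple[tuple[str, str], bool]] = []
    for a, b in order:
        if a in used_a or b in used_b or corr((a, b)) == -math.inf:
            continue
        used_a.add(a)
        used_b.add(b)
        r = corr((a, b))
        competitors = [
            corr(p)
            for p in candidate_pairs
            if p != (a, b) and (p[0] == a or p[1] == b)
        ]
        flagged = r >= r_min and all(
            c == -math.inf or r - c >= margin for c in competitors
        )
        out.append((((a, b)), flagged))
    return sorted(out)
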