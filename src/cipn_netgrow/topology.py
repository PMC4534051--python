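"""Post-hoc network diagnostics: connection counts, hubs, power-law check.

Highly connected molecules (hubs) in a generated network are taken as
markers of potential biological importance; the published convention is a
threshold of at least 15 connections inside the network.  The scale-free
question — does the degree distribution follow a power law? — is examined
the way it usually is in this literature: ordinary least squares on the
log-log degree-frequency plot.  A straight decaying line is consistent
with a power law; the fit reports slope, intercept and R² and deliberately
emits no scale-free yes/no verdict, because a bounded, size-capped network
generator cannot guarantee scale-freeness.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import networkx as nx
from scipy import stats

__all__ = [
    "HubReport",
    "PowerLawFit",
    "count_connections",
    "find_hubs",
    "loglog_powerlaw_fit",
]


@dataclass
class HubReport:
    """Genes meeting the connection threshold, with focus flags.

    ``entries`` are (gene, connections, is_focus), sorted by descending
    connections then gene id.
    """

    min_connections: int
    entries: list[tuple[str, int, bool]]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return [g for g, _, _ in self.entries]


@dataclass
class PowerLawFit:
    """OLS fit of log10 frequency against log10 degree."""

    slope: float
    intercept: float
    r_squared: float
    points: list[tuple[float, float]]


def count_connections(net: nx.Graph) -> dict[str, int]:
    """Connections (simple-view degree) of each gene within the network,
    in descending order of count (gene id breaking ties)."""
    counts = dict(net.degree())
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def find_hubs(
    counts: Mapping[str, int],
    min_connections: int = 15,
    focus_genes: Iterable[str] = (),
) -> HubReport:
    """Genes with at least ``min_connections`` connections, focus-flagged.

    Monotone in the threshold: raising it can only remove entries.
    """
    if min_connections < 0:
        raise ValueError("min_connections must be >= 0")
    focus = set(focus_genes)
    entries = [
        (g, c, g in focus)
        for g, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if c >= min_connections
    ]
    return HubReport(min_connections=min_connections, entries=entries)


def loglog_powerlaw_fit(
    degrees: Iterable[int], mode: str = "frequency"
) -> PowerLawFit:
    """Least-squares line through the log-log degree distribution.

    ``mode="frequency"`` fits log10 freq(k) on log10 k over degrees k >= 1
    with freq(k) >= 1 (the conventional raw plot).  ``mode="ccdf"`` fits
    the complementary cumulative distribution instead, which is less noisy
    in the tail.  At least 3 distinct positive degrees are required.
    """
    counter = Counter(int(k) for k in degrees if k >= 1)
    ks = np.array(sorted(counter), dtype=float)
    if len(ks) < 3:
        raise ValueError(
            f"need at least 3 distinct positive degrees, got {len(ks)}"
        )
    freq = np.array([counter[int(k)] for k in ks], dtype=float)
    if mode == "frequency":
        y = freq
    elif mode == "ccdf":
        total = freq.sum()
        y = (total - np.concatenate(([0.0], np.cumsum(freq)[:-1]))) / total
    else:
        raise ValueError(f"unknown mode {mode!r}")
    x_log = np.log10(ks)
    y_log = np.log10(y)
    fit = stats.linregress(x_log, y_log)
    return PowerLawFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        points=list(zip(x_log.tolist(), y_log.tolist())),
    )
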