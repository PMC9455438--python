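"""Variable importance in projection (VIP) and cross-dataset intersection.

The VIP score of channel j aggregates its squared PLS weights over the A
components, each weighted by the Y-variance that component explains:

    VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a ),
    SS_a  = (c_a' c_a)(t_a' t_a)

With unit-norm weight columns the mean of VIP^2 over the p channels is
exactly 1, so VIP > 1 ("more important than average") is the standard
selection rule.  Several VIP generalisations exist for multi-response PLS;
this is the most widely used form and the only one satisfying the
mean-square-one identity used here as a correctness invariant.

Channel indices are 0-based in code; human-readable tables additionally
carry the 1-based index and the channel energy in keV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .plsda_core import PLSDAModel

__all__ = [
    "VIPResult",
    "IntersectionSummary",
    "vip_scores",
    "select_vip",
    "intersect_selected",
]


@dataclass
class VIPResult:
    """Per-channel VIP scores of one fitted model with its VIP>1 selection."""

    channel_energies: np.ndarray
    vip: np.ndarray
    threshold: float
    selected: np.ndarray  # sorted 0-based channel indices with vip > threshold
    model_settings: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return int(self.vip.size)

    @property
    def selected_fraction(self) -> float:
        return self.selected.size / self.p

    def to_frame(self) -> pd.DataFrame:
        sel = np.zeros(self.p, dtype=bool)
        sel[self.selected] = True
        return pd.DataFrame(
            {
                "channel": np.arange(1, self.p + 1),  # 1-based for humans
                "energy_kev": self.channel_energies,
                "vip": self.vip,
                "selected": sel,
            }
        )


def vip_scores(
    m: PLSDAModel,
    channel_energies: np.ndarray | None = None,
    threshold: float = 1.0,
) -> VIPResult:
    """VIP scores of every channel for a fitted PLS-DA model."""
    if m.A < 1 or m.W.shape[1] < 1:
        raise ValueError("model has no fitted components")
    ss = m.component_y_variance()  # (A,)
    ss_total = ss.sum()
    if ss_total == 0:
        raise ValueError("model explains no response variance")
    p = m.p
    vip = np.sqrt(p * (m.W**2 @ ss) / ss_total)
    if channel_energies is None:
        channel_energies = np.arange(p, dtype=float)
    result = VIPResult(
        channel_energies=np.asarray(channel_energies, float),
        vip=vip,
        threshold=threshold,
        selected=np.array([], dtype=int),
        model_settings={
            "A": m.A,
            "autoscale": m.autoscale,
            "class_labels": m.class_labels,
            "vip_variant": "explained-Y-variance weighted (SS_a = c_a'c_a t_a't_a)",
        },
    )
    result.selected = select_vip(result, threshold)
    return result


def select_vip(v: VIPResult, threshold: float = 1.0) -> np.ndarray:
    """Channels with VIP strictly above the threshold, ascending 0-based."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return np.flatnonzero(v.vip > threshold)


@dataclass
class IntersectionSummary:
    """Set algebra over the VIP-selected channels of several datasets.

    ``region_counts`` is the full Venn decomposition: for every non-empty
    subset of datasets, the number of channels selected in exactly those
    datasets.  ``shared_all`` counts channels selected in every dataset and
    ``unique`` those private to a single one; fractions are relative to the
    common channel count p.
    """

    dataset_names: list[str]
    p: int
    selected_counts: dict[str, int]
    shared_all: int
    shared_all_fraction: float
    unique: dict[str, int]
    unique_fractions: dict[str, float]
    region_counts: dict[tuple[str, ...], int]

    def to_dict(self) -> dict:
        return {
            "dataset_names": self.dataset_names,
            "n_channels": self.p,
            "selected_counts": self.selected_counts,
            "shared_all": self.shared_all,
            "shared_all_fraction": self.shared_all_fraction,
            "unique_counts": self.unique,
            "unique_fractions": self.unique_fractions,
            "region_counts": {
                "|".join(names): count for names, count in self.region_counts.items()
            },
        }


def intersect_selected(results: dict[str, VIPResult]) -> IntersectionSummary:
    """Venn-style overlap of VIP-selected channel sets across datasets.

    All datasets must share the channel axis.  Counts are exact set
    algebra; each is also reported as a fraction of p, matching how shared
    and species-unique feature counts are usually quoted.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 datasets to intersect")
    names = list(results)
    first = results[names[0]]
    for name in names[1:]:
        other = results[name]
        if other.p != first.p or not np.allclose(
            other.channel_energies, first.channel_energies
        ):
            raise ValueError(f"dataset {name!r} has a different channel axis")

    sets = {name: set(results[name].selected.tolist()) for name in names}
    shared_all = set.intersection(*sets.values())
    region_counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo))
            region_counts[combo] = len(inside - outside)
    unique = {name: region_counts[(name,)] for name in names}
    p = first.p
    return IntersectionSummary(
        dataset_names=names,
        p=p,
        selected_counts={name: len(sets[name]) for name in names},
        shared_all=len(shared_all),
        shared_all_fraction=len(shared_all) / p,
        unique=unique,
        unique_fractions={name: unique[name] / p for name in names},
        region_counts=region_counts,
    )
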