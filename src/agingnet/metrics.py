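"""Connectivity-strength statistics at the lobe and region-to-lobe level.

Connectivity strength between two lobes is the average edge weight over all
region pairs spanning them; within a single lobe it is the average over
unordered off-diagonal pairs.  Networks are unthresholded, so zero-weight
(absent) structural connections contribute to the average rather than being
dropped.  Lobes pool both hemispheres.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import Atlas, Lobe
from .netbuild import ConnectivityMatrix

#: The five prefrontal-posterior lobe pairs examined together.
PFC_POSTERIOR_PAIRS: tuple[tuple[Lobe, Lobe], ...] = (
    (Lobe.PREFRONTAL, Lobe.LATERAL_TEMPORAL),
    (Lobe.PREFRONTAL, Lobe.MEDIAL_TEMPORAL),
    (Lobe.PREFRONTAL, Lobe.PARIETAL),
    (Lobe.PREFRONTAL, Lobe.OCCIPITAL),
    (Lobe.PREFRONTAL, Lobe.MOTOR_SENSORY),
)

#: The three occipital-posterior lobe pairs examined together.
OCCIPITAL_POSTERIOR_PAIRS: tuple[tuple[Lobe, Lobe], ...] = (
    (Lobe.OCCIPITAL, Lobe.LATERAL_TEMPORAL),
    (Lobe.OCCIPITAL, Lobe.MEDIAL_TEMPORAL),
    (Lobe.OCCIPITAL, Lobe.PARIETAL),
)

PAIR_PRESETS: Mapping[str, tuple[tuple[Lobe, Lobe], ...]] = {
    "pfc_posterior": PFC_POSTERIOR_PAIRS,
    "occipital_posterior": OCCIPITAL_POSTERIOR_PAIRS,
}


def _check_lobe(atlas: Atlas, lobe: Lobe | str) -> list[int]:
    lobe = Lobe(lobe)
    idx = atlas.lobe_indices(lobe)
    if not idx:
        raise ValueError(f"lobe {lobe.value!r} has no regions in this atlas")
    return idx


def lobe_strength(
    w: ConnectivityMatrix, atlas: Atlas, lobe_a: Lobe | str, lobe_b: Lobe | str
) -> float:
    """Mean edge weight between two lobes (or within one, off-diagonal)."""
    if w.n_regions != atlas.n_regions:
        raise ValueError(
            f"matrix is {w.n_regions}x{w.n_regions} but atlas has {atlas.n_regions} regions"
        )
    ia = _check_lobe(atlas, lobe_a)
    ib = _check_lobe(atlas, lobe_b)
    block = w.weights[np.ix_(ia, ib)]
    if Lobe(lobe_a) is Lobe(lobe_b):
        n = len(ia)
        if n < 2:
            raise ValueError(f"within-lobe strength needs >= 2 regions in {lobe_a}")
        mask = ~np.eye(n, dtype=bool)
        return float(block[mask].mean())
    return float(block.mean())


def region_to_lobe_strength(
    w: ConnectivityMatrix,
    atlas: Atlas,
    region_name: str,
    lobe_b: Lobe | str,
    bilateral: bool = True,
    hemisphere: str | None = None,
) -> float:
    """Mean weight between a named region and all regions of a lobe.

    With ``bilateral=True`` (default) both hemisphere instances of the named
    region are pooled; otherwise ``hemisphere`` selects one.  Pairs of a
    region with itself are excluded, so the statistic is well defined when
    the lobe contains the region.
    """
    if bilateral:
        sources = atlas.region_instances(region_name)
    else:
        if hemisphere is None:
            raise ValueError("hemisphere required when bilateral=False")
        sources = [atlas.region(region_name, hemisphere)]
    ib = _check_lobe(atlas, lobe_b)
    vals = [
        w.weights[r.index, j] for r in sources for j in ib if j != r.index
    ]
    if not vals:
        raise ValueError(
            f"no region pairs between {region_name!r} and lobe {Lobe(lobe_b).value!r}"
        )
    return float(np.mean(vals))


def strength_table(
    networks: Iterable[ConnectivityMatrix],
    atlas: Atlas,
    pairs: Sequence[tuple[Lobe | str, Lobe | str]],
) -> pd.DataFrame:
    """Long-format table: one row per subject x modality x lobe pair.

    Columns: ``subject_id, modality, unit_a, unit_b, strength``.  Row order is
    deterministic: networks in input order, pairs in list order.
    """
    rows = []
    for net in networks:
        for lobe_a, lobe_b in pairs:
            rows.append(
                {
                    "subject_id": net.subject_id,
                    "modality": net.modality.value,
                    "unit_a": Lobe(lobe_a).value,
                    "unit_b": Lobe(lobe_b).value,
                    "strength": lobe_strength(net, atlas, lobe_a, lobe_b),
                }
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "modality", "unit_a", "unit_b", "strength"]
    )


def region_strength_table(
    networks: Iterable[ConnectivityMatrix],
    atlas: Atlas,
    pairs: Sequence[tuple[str, Lobe | str]],
) -> pd.DataFrame:
    """Like :func:`strength_table` but for (region name, lobe) pairs."""
    rows = []
    for net in networks:
        for region_name, lobe_b in pairs:
            rows.append(
                {
                    "subject_id": net.subject_id,
                    "modality": net.modality.value,
                    "unit_a": region_name,
                    "unit_b": Lobe(lobe_b).value,
                    "strength": region_to_lobe_strength(net, atlas, region_name, lobe_b),
                }
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "modality", "unit_a", "unit_b", "strength"]
    )
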