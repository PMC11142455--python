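"""Parcellation scheme: ROI identities, 9-network membership, canonical order.

The analysis operates on parcellated time series: 400 cortical regions
(Schaefer-style) plus 30 subcortical regions, grouped into nine functional
networks.  The canonical ordering sorts ROIs by network so that the main
diagonal blocks of an FC matrix are intranetwork edges and off-diagonal
blocks are internetwork edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

#: Canonical network order.  ECN = executive control, DMN = default mode,
#: DAN = dorsal attention, LN = limbic, SN = salience/ventral attention,
#: SMN = somatomotor, TP = temporal-parietal, VIS = visual, SUB = subcortical.
NETWORKS = ("ECN", "DMN", "DAN", "LN", "SN", "SMN", "TP", "VIS", "SUB")

#: Default ROI counts per network: 400 cortical + 30 subcortical = 430.
DEFAULT_NETWORK_SIZES = {
    "ECN": 61,
    "DMN": 91,
    "DAN": 46,
    "LN": 26,
    "SN": 47,
    "SMN": 55,
    "TP": 12,
    "VIS": 62,
    "SUB": 30,
}


@dataclass(frozen=True)
class ParcellationScheme:
    """ROI names and network assignments in canonical network-sorted order.

    ``roi_names[i]`` is the name of the ROI at canonical position ``i``;
    ``networks[i]`` its network label.  ROI ids are the 0-based canonical
    positions themselves.
    """

    roi_names: tuple[str, ...]
    networks: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.roi_names) != len(self.networks):
            raise SchemaError("roi_names and networks length mismatch")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise SchemaError("duplicate ROI names in parcellation")
        unknown = set(self.networks) - set(NETWORKS)
        if unknown:
            raise SchemaError(f"unknown network labels: {sorted(unknown)}")
        # canonical order groups ROIs by network contiguously
        seen: list[str] = []
        for net in self.networks:
            if seen and seen[-1] != net and net in seen:
                raise SchemaError(f"network {net} not contiguous in ordering")
            if not seen or seen[-1] != net:
                seen.append(net)
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.roi_names)})

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def network_labels(self) -> tuple[str, ...]:
        """Networks present, in canonical order."""
        return tuple(n for n in NETWORKS if n in set(self.networks))

    def network_indices(self, network: str) -> np.ndarray:
        """Canonical ROI indices belonging to ``network``."""
        return np.flatnonzero(np.asarray(self.networks) == network)

    def index_of(self, roi_name: str) -> int:
        try:
            return self._index[roi_name]
        except KeyError:
            raise SchemaError(f"ROI {roi_name!r} not in parcellation") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"roi_name": self.roi_names, "network": self.networks},
            index=pd.RangeIndex(self.n_rois, name="roi_id"),
        )


def make_scheme(network_sizes: dict[str, int] | None = None) -> ParcellationScheme:
    """Build a scheme with ``network_sizes`` ROIs per network (canonical order).

    Defaults to the full 430-ROI layout.  ROI names are synthetic
    (``<NET>_<k>``); real lookups are loaded with :func:`read_scheme`.
    """
    sizes = dict(DEFAULT_NETWORK_SIZES if network_sizes is None else network_sizes)
    names: list[str] = []
    nets: list[str] = []
    for net in NETWORKS:
        if net not in sizes:
            continue
        for k in range(sizes[net]):
            names.append(f"{net}_{k + 1:03d}")
            nets.append(net)
    return ParcellationScheme(tuple(names), tuple(nets))


def reduced_scheme(n_rois: int, seed: int | None = None) -> ParcellationScheme:
    """A scheme with ``n_rois`` total, allocated to the 9 networks
    proportionally to the default layout (each network keeps ≥3 ROIs so
    every intra edge set stays valid)."""
    total = sum(DEFAULT_NETWORK_SIZES.values())
    sizes = {
        net: max(3, int(round(n_rois * c / total)))
        for net, c in DEFAULT_NETWORK_SIZES.items()
    }
    # trim/grow largest networks to hit the exact count
    diff = sum(sizes.values()) - n_rois
    order = sorted(sizes, key=sizes.get, reverse=True)
    i = 0
    while diff != 0:
        net = order[i % len(order)]
        if diff > 0 and sizes[net] > 3:
            sizes[net] -= 1
            diff -= 1
        elif diff < 0:
            sizes[net] += 1
            diff += 1
        i += 1
    return make_scheme(sizes)


def read_scheme(path) -> ParcellationScheme:
    """Load a two-column lookup TSV (roi_name, network); rows are taken in
    file order, which must already be network-contiguous."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"roi_name", "network"} <= set(df.columns):
        raise SchemaError(f"parcellation file needs roi_name/network columns, got {list(df.columns)}")
    return ParcellationScheme(tuple(df["roi_name"]), tuple(df["network"]))


def write_scheme(scheme: ParcellationScheme, path) -> None:
    scheme.to_frame().to_csv(path, sep="\t", index=False)
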