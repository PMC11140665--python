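"""Node-to-network parcellation handling.

The default scheme mirrors a 415-node cortical + subcortical parcellation
grouped into nine functional networks: the 17-network cortical subnetworks
collapsed into eight networks (Default Mode A/B/C as one network, etc.)
plus the subcortical nodes as their own ninth network. The per-network node
counts shipped here are nominal proportions for the 400-parcel cortical
scheme; scaled-down parcellations allocate nodes proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NINE_NETWORKS = (
    "Visual",
    "SomMot",
    "DorsAttn",
    "SalVentAttn",
    "Limbic",
    "Control",
    "DMN",
    "TempPar",
    "Subcortical",
)

# Nominal node counts at the reference 415-node resolution.
DEFAULT_NETWORK_SIZES = {
    "Visual": 61,
    "SomMot": 77,
    "DorsAttn": 46,
    "SalVentAttn": 47,
    "Limbic": 26,
    "Control": 61,
    "DMN": 73,
    "TempPar": 9,
    "Subcortical": 15,
}


@dataclass
class Parcellation:
    """Lookup mapping node ids to labels, networks, and hemispheres."""

    table: pd.DataFrame  # columns: node_id, label, network, hemisphere

    def __post_init__(self) -> None:
        required = {"node_id", "label", "network", "hemisphere"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"parcellation missing columns: {sorted(missing)}")
        ids = self.table["node_id"].to_numpy()
        if not np.array_equal(np.sort(ids), np.arange(len(ids))):
            raise ValueError("node_id must be a permutation of 0..n-1")
        self.table = self.table.sort_values("node_id").reset_index(drop=True)

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> list[str]:
        seen: list[str] = []
        for net in self.table["network"]:
            if net not in seen:
                seen.append(net)
        return seen

    @property
    def network_of_node(self) -> np.ndarray:
        return self.table["network"].to_numpy()

    def network_indices(self) -> dict[str, np.ndarray]:
        return {
            net: np.flatnonzero(self.table["network"].to_numpy() == net)
            for net in self.networks
        }

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Parcellation":
        return cls(pd.read_csv(path, sep="\t"))


def _proportional_counts(n_nodes: int, networks: tuple[str, ...]) -> dict[str, int]:
    """Largest-remainder allocation of nodes across networks (each >= 1)."""
    props = np.array([DEFAULT_NETWORK_SIZES[n] for n in networks], dtype=float)
    props /= props.sum()
    raw = props * n_nodes
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() > n_nodes:
        k = int(np.argmax(counts))
        counts[k] -= 1
    remainder = raw - np.floor(raw)
    order = np.argsort(-remainder)
    i = 0
    while counts.sum() < n_nodes:
        counts[order[i % len(order)]] += 1
        i += 1
    return dict(zip(networks, (int(c) for c in counts)))


def build_parcellation(n_nodes: int = 415, networks: tuple[str, ...] = NINE_NETWORKS) -> Parcellation:
    """Build a parcellation of ``n_nodes`` nodes over the given networks.

    Nodes are assigned round-robin across networks, with each network's
    quota proportional to its nominal node count at the reference 415-node
    resolution, so scaled-down parcellations keep the same composition.
    """
    if n_nodes < len(networks):
        raise ValueError("need at least one node per network")
    counts = _proportional_counts(n_nodes, networks)
    remaining = dict(counts)
    rows = []
    node_id = 0
    while node_id < n_nodes:
        for net in networks:
            if remaining[net] > 0:
                hemi = "LH" if node_id % 2 == 0 else "RH"
                rows.append(
                    {
                        "node_id": node_id,
                        "label": f"{hemi}_{net}_{counts[net] - remaining[net] + 1}",
                        "network": net,
                        "hemisphere": hemi,
                    }
                )
                remaining[net] -= 1
                node_id += 1
                if node_id == n_nodes:
                    break
    return Parcellation(pd.DataFrame(rows))
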