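"""Ascendancy of a flow network as average mutual information, with its
entropy capacity and overhead.

Flows F_ij from compartment i to j induce a joint distribution
p(a_i, b_j) = F_ij / sum(F). Ascendancy (here in bits, K = 1) is

    As = K * sum_ij p(a_i, b_j) * log2[ p(b_j | a_i) / p(b_j) ]

i.e. the mutual information between flow sources and destinations.
Capacity is the joint entropy -K * sum p log2 p; the difference
(overhead) measures path multiplicity/redundancy, commonly associated
with resilience. Optionally K can be the total system throughput,
giving the throughput-scaled ascendancy of ecological network analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["FlowNetwork", "AscendancyReport", "flow_probabilities", "ascendancy_ami", "read_flow_network"]


@dataclass
class FlowNetwork:
    """Square nonnegative inter-compartment flow matrix with labels."""

    labels: list[str]
    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2 or self.F.shape[0] != self.F.shape[1]:
            raise ValueError(f"flow matrix must be square, got shape {self.F.shape}")
        if len(self.labels) != self.F.shape[0]:
            raise ValueError("one label per compartment required")
        if np.any(self.F < 0) or not np.all(np.isfinite(self.F)):
            raise ValueError("flows must be finite and nonnegative")
        if self.F.sum() <= 0:
            raise ValueError("total flow must be positive")

    @property
    def n(self) -> int:
        return self.F.shape[0]

    @property
    def total_throughput(self) -> float:
        return float(self.F.sum())


@dataclass(frozen=True)
class AscendancyReport:
    """AMI-based ascendancy with capacity and overhead (same units)."""

    ami: float
    capacity: float
    overhead: float
    K: float

    def __post_init__(self) -> None:
        if self.ami < -1e-9 or self.capacity < -1e-9:
            raise ValueError("ami and capacity must be nonnegative")
        if self.overhead < -1e-9:
            raise ValueError("overhead must be nonnegative")


def flow_probabilities(net: FlowNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint p(a_i, b_j) = F_ij / sum(F) and the two marginals."""
    joint = net.F / net.F.sum()
    return joint, joint.sum(axis=1), joint.sum(axis=0)


def ascendancy_ami(net: FlowNetwork, K: float | str = 1.0) -> AscendancyReport:
    """Ascendancy, capacity and overhead of a flow network.

    Parameters
    ----------
    net : FlowNetwork
    K : float or "throughput"
        Scaling constant (default 1: plain AMI in bits). The string
        "throughput" uses the total system throughput, yielding the
        throughput-scaled form.
    """
    if K == "throughput":
        K = net.total_throughput
    K = float(K)
    if K <= 0:
        raise ValueError("K must be positive")
    joint, p_src, p_dst = flow_probabilities(net)
    nz = joint > 0
    ami = float(np.sum(joint[nz] * np.log2(joint[nz] / np.outer(p_src, p_dst)[nz])))
    capacity = float(-np.sum(joint[nz] * np.log2(joint[nz])))
    ami = max(ami, 0.0)  # clip -0.0 / rounding
    return AscendancyReport(ami=K * ami, capacity=K * capacity, overhead=K * (capacity - ami), K=K)


def read_flow_network(path) -> FlowNetwork:
    """Read a flow network from a labeled square CSV matrix or a TSV edge
    list (``source<TAB>target<TAB>flow``, no header)."""
    path = Path(path)
    if path.suffix.lower() == ".tsv":
        labels: list[str] = []
        edges = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) != 3:
                    raise ValueError(f"edge list rows need 3 fields, got {row}")
                src, dst, w = row[0], row[1], float(row[2])
                for lab in (src, dst):
                    if lab not in labels:
                        labels.append(lab)
                edges.append((src, dst, w))
        F = np.zeros((len(labels), len(labels)))
        for src, dst, w in edges:
            F[labels.index(src), labels.index(dst)] += w
        return FlowNetwork(labels, F)
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValueError("matrix CSV must have identical row and column labels")
    return FlowNetwork(labels, df.to_numpy(dtype=float))
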