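"""Connectivity builders for random balanced and clustered networks.

All builders draw a Bernoulli graph per ordered pair (no autapses) and set
connected entries to the calibrated base weight of the population pair.
Clustering multiplies weights — not connection probabilities — by the
within/across factors of a :class:`~eiclust.params.ClusterScaling`, which
preserves the population-mean weight of every synapse class exactly.

Unit ordering convention: excitatory units come first (ids 0..N_E-1), then
inhibitory units (N_E..N-1).  Cluster membership is assigned in contiguous
index blocks for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .params import NetworkSpec, ClusterScaling
from .calibration import compute_weights

__all__ = [
    "ClusterAssignment", "ConnectivityMatrix",
    "build_random_balanced", "build_e_clustered", "build_ei_clustered",
    "build_e_plus_i_variant",
]


@dataclass(frozen=True)
class ClusterAssignment:
    """Population label and cluster index per unit (-1 = unclustered)."""

    population: np.ndarray   # array of 'E'/'I'
    cluster: np.ndarray      # int cluster id, -1 if not clustered

    @property
    def n_units(self) -> int:
        return len(self.population)

    def units_of_cluster(self, q: int, population: str = "E") -> np.ndarray:
        return np.where((self.cluster == q)
                        & (self.population == population))[0]


def _assign(spec: NetworkSpec, Q: Optional[int],
            cluster_I: bool) -> ClusterAssignment:
    N_E, N_I = spec.N_E, spec.N_I
    population = np.array(["E"] * N_E + ["I"] * N_I)
    cluster = np.full(N_E + N_I, -1, dtype=np.int64)
    if Q is not None:
        if N_E % Q:
            raise ValueError(f"N_E={N_E} not divisible by Q={Q}")
        cluster[:N_E] = np.arange(N_E) // (N_E // Q)
        if cluster_I:
            if N_I % Q:
                raise ValueError(f"N_I={N_I} not divisible by Q={Q}")
            cluster[N_E:] = np.arange(N_I) // (N_I // Q)
    return ClusterAssignment(population=population, cluster=cluster)


@dataclass
class ConnectivityMatrix:
    """Signed, weighted synaptic connectivity.

    ``weights[i, j]`` is the efficacy (pA) from presynaptic j to
    postsynaptic i.  CSC format gives fast access to the targets of one
    presynaptic unit, which is what the simulator needs.
    """

    weights: sp.csc_matrix
    assignment: ClusterAssignment
    kind: str
    seed: Optional[int]

    @property
    def n_units(self) -> int:
        return self.weights.shape[0]

    def to_csv(self, edges_path, units_path) -> None:
        coo = self.weights.tocoo()
        pd.DataFrame({"pre_id": coo.col, "post_id": coo.row,
                      "weight_pA": coo.data}).to_csv(edges_path, index=False)
        pd.DataFrame({"unit_id": np.arange(self.n_units),
                      "population": self.assignment.population,
                      "cluster": self.assignment.cluster}
                     ).to_csv(units_path, index=False)

    @classmethod
    def from_csv(cls, edges_path, units_path,
                 kind: str = "imported") -> "ConnectivityMatrix":
        edges = pd.read_csv(edges_path, float_precision="round_trip")
        units = pd.read_csv(units_path).sort_values("unit_id")
        n = len(units)
        w = sp.csc_matrix(
            (edges["weight_pA"], (edges["post_id"], edges["pre_id"])),
            shape=(n, n))
        assignment = ClusterAssignment(
            population=units["population"].to_numpy(),
            cluster=units["cluster"].to_numpy())
        return cls(weights=w, assignment=assignment, kind=kind, seed=None)


def _bernoulli_block(rng: np.random.Generator, n_post: int, n_pre: int,
                     p: float, post_off: int, pre_off: int,
                     exclude_diag: bool):
    """Row/col index arrays of a Bernoulli(p) block; excludes autapses when
    the block lies on the diagonal."""
    mask = rng.random((n_post, n_pre)) < p
    if exclude_diag and post_off == pre_off:
        np.fill_diagonal(mask, False)
    rows, cols = np.nonzero(mask)
    return rows + post_off, cols + pre_off


def _build(spec: NetworkSpec, scaling: Optional[ClusterScaling], seed,
           kind: str, scale_E: bool, scale_I_pairs: tuple[str, ...],
           cluster_I: bool) -> ConnectivityMatrix:
    """Shared machinery: draw the four Bernoulli blocks, then apply cluster
    scaling to the requested synapse classes."""
    rng = np.random.default_rng(seed)
    w = compute_weights(spec.neuron, spec.synapse)
    N_E = spec.N_E
    Q = scaling.Q if scaling is not None else None
    assignment = _assign(spec, Q, cluster_I=cluster_I)
    cluster = assignment.cluster

    offsets = {"E": 0, "I": N_E}
    sizes = {"E": N_E, "I": spec.N_I}
    rows_all, cols_all, data_all = [], [], []
    # fixed draw order keeps matrices comparable across topology kinds
    for post in ("E", "I"):
        for pre in ("E", "I"):
            rows, cols = _bernoulli_block(
                rng, sizes[post], sizes[pre], spec.synapse.p(post, pre),
                offsets[post], offsets[pre], exclude_diag=True)
            data = np.full(rows.shape, w.J(post, pre))
            if scaling is not None:
                pair = f"{post}{pre}"
                same = (cluster[rows] == cluster[cols]) \
                    & (cluster[rows] >= 0) & (cluster[cols] >= 0)
                if pair == "EE" and scale_E:
                    data = np.where(same, data * scaling.J_Eplus,
                                    data * scaling.J_Eminus)
                elif pair in scale_I_pairs:
                    data = np.where(same, data * scaling.J_Iplus,
                                    data * scaling.J_Iminus)
            rows_all.append(rows)
            cols_all.append(cols)
            data_all.append(data)

    n = spec.N
    mat = sp.csc_matrix(
        (np.concatenate(data_all),
         (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n, n))
    return ConnectivityMatrix(weights=mat, assignment=assignment,
                              kind=kind, seed=seed)


def build_random_balanced(spec: NetworkSpec, seed=None) -> ConnectivityMatrix:
    """Unstructured balanced network: Bernoulli graph with base weights."""
    return _build(spec, None, seed, "random_balanced",
                  scale_E=False, scale_I_pairs=(), cluster_I=False)


def build_e_clustered(spec: NetworkSpec, scaling: ClusterScaling,
                      seed=None) -> ConnectivityMatrix:
    """Excitatory clustering only: E->E weights scaled by J_Eplus within a
    cluster and J_Eminus across; inhibition stays unstructured (the
    "blanket of inhibition" architecture)."""
    return _build(spec, scaling, seed, "e_clustered",
                  scale_E=True, scale_I_pairs=(), cluster_I=False)


def build_ei_clustered(spec: NetworkSpec, scaling: ClusterScaling,
                       seed=None) -> ConnectivityMatrix:
    """Joint E/I clustering: each excitatory cluster is paired with an
    inhibitory cluster, and the E->I, I->E and I->I weights between paired
    clusters are potentiated by J_Iplus (depressed by J_Iminus across)."""
    return _build(spec, scaling, seed, "ei_clustered",
                  scale_E=True, scale_I_pairs=("EI", "IE", "II"),
                  cluster_I=True)


def build_e_plus_i_variant(spec: NetworkSpec, scaling: ClusterScaling,
                           seed=None) -> ConnectivityMatrix:
    """Variant with unidirectional E->I selectivity: each excitatory
    cluster preferentially excites one disjoint inhibitory pool (I->E and
    I->I remain unstructured), alongside the usual E->E clustering."""
    return _build(spec, scaling, seed, "e_plus_i",
                  scale_E=True, scale_I_pairs=("IE",), cluster_I=True)
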