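"""FC similarity: the core reconfiguration statistic.

Similarity between two conditions is the Pearson correlation (Fisher
r-to-z transformed) of their FC matrices vectorized over an edge set:
the global lower triangle, one network's intranetwork edges (both
endpoints inside), or one network's internetwork edges (exactly one
endpoint inside).  High similarity = little reconfiguration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import FCMatrix, fisher_z
from .errors import DataError, ScopeError, StateError
from .parcellation import ParcellationScheme

REST_TASK_PAIRS = (("dot1", "rest"), ("dot3", "rest"), ("dot5", "rest"))
STEPWISE_PAIRS = (("dot1", "rest"), ("dot3", "dot1"), ("dot5", "dot3"))
MIN_EDGES = 3


@dataclass(frozen=True)
class EdgeSet:
    """scope ∈ {global, intra:<net>, inter:<net>}; (i, j) index pairs, i > j."""

    scope: str
    rows: np.ndarray
    cols: np.ndarray

    def __len__(self) -> int:
        return len(self.rows)

    def extract(self, fc: FCMatrix) -> np.ndarray:
        return fc.values[self.rows, self.cols]


def build_edge_sets(scheme: ParcellationScheme) -> dict[str, EdgeSet]:
    """Global + per-network intra/inter edge sets.

    Every cross-network edge appears in both endpoint networks' inter sets,
    so Σ|intra| + ½Σ|inter| = R(R−1)/2.
    """
    R = scheme.n_rois
    rows, cols = np.tril_indices(R, k=-1)
    nets = np.asarray(scheme.networks)
    out = {"global": EdgeSet("global", rows, cols)}
    for net in scheme.network_labels:
        in_net_r = nets[rows] == net
        in_net_c = nets[cols] == net
        intra = in_net_r & in_net_c
        inter = in_net_r ^ in_net_c
        out[f"intra:{net}"] = EdgeSet(f"intra:{net}", rows[intra], cols[intra])
        out[f"inter:{net}"] = EdgeSet(f"inter:{net}", rows[inter], cols[inter])
    return out


def similarity(fc_a: FCMatrix, fc_b: FCMatrix, edge_set: EdgeSet) -> tuple[float, float]:
    """(r, z) Pearson similarity of the two matrices over the edge set."""
    if fc_a.scheme is not fc_b.scheme and fc_a.scheme != fc_b.scheme:
        raise StateError("FC matrices built on different parcellation schemes")
    if len(edge_set) < MIN_EDGES:
        raise ScopeError(
            f"{edge_set.scope}: only {len(edge_set)} edges, need ≥{MIN_EDGES}"
        )
    va, vb = edge_set.extract(fc_a), edge_set.extract(fc_b)
    if va.std() == 0 or vb.std() == 0:
        raise DataError(f"{edge_set.scope}: zero-variance edge vector")
    r = float(np.corrcoef(va, vb)[0, 1])
    return r, float(fisher_z(r))


def _pair_records(subject: str, fcs: dict[str, FCMatrix], scheme: ParcellationScheme,
                  pairs, comparison: str) -> pd.DataFrame:
    edge_sets = build_edge_sets(scheme)
    rows = []
    for hi, lo in pairs:
        for name, es in edge_sets.items():
            rec = {
                "subject": subject, "comparison": comparison,
                "pair": f"{hi}-{lo}", "scope": name,
                "n_edges": len(es), "r": np.nan, "z": np.nan, "reason": "",
            }
            try:
                rec["r"], rec["z"] = similarity(fcs[hi], fcs[lo], es)
            except ScopeError as exc:
                rec["reason"] = str(exc)
            except KeyError as exc:
                raise StateError(f"{subject}: missing condition {exc} for {comparison}") from None
            rows.append(rec)
    return pd.DataFrame(rows)


def rest_task_similarities(subject: str, fcs: dict[str, FCMatrix],
                           scheme: ParcellationScheme) -> pd.DataFrame:
    """3 load pairs × (1 global + 9 intra + 9 inter) similarity records."""
    return _pair_records(subject, fcs, scheme, REST_TASK_PAIRS, "rest_task")


def stepwise_similarities(subject: str, fcs: dict[str, FCMatrix],
                          scheme: ParcellationScheme) -> pd.DataFrame:
    """Adjacent-demand pairs: dot1–rest, dot3–dot1, dot5–dot3."""
    return _pair_records(subject, fcs, scheme, STEPWISE_PAIRS, "stepwise")


def within_load_similarity(subject: str, fcs: dict[str, FCMatrix],
                           scheme: ParcellationScheme) -> pd.DataFrame:
    """Global run1-vs-run2 similarity at each load (stability control)."""
    es = build_edge_sets(scheme)["global"]
    rows = []
    for load in (1, 3, 5):
        a, b = f"dot{load}_run1", f"dot{load}_run2"
        if a not in fcs or b not in fcs:
            raise StateError(f"{subject}: per-run FC {a}/{b} missing for within-load mode")
        r, z = similarity(fcs[a], fcs[b], es)
        rows.append({
            "subject": subject, "comparison": "within_load",
            "pair": f"dot{load}r1-dot{load}r2", "scope": "global",
            "n_edges": len(es), "r": r, "z": z, "reason": "",
        })
    return pd.DataFrame(rows)


def averaged_fc(fc: FCMatrix, scheme: ParcellationScheme) -> pd.DataFrame:
    """Mean Fisher-z FC per edge set: 1 global + 9 intra + 9 inter values."""
    rows = []
    for name, es in build_edge_sets(scheme).items():
        if len(es) < 1:
            raise ScopeError(f"{name}: empty edge set")
        rows.append({
            "condition": fc.condition, "scope": name,
            "n_edges": len(es), "mean_z": float(es.extract(fc).mean()),
        })
    return pd.DataFrame(rows)
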