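"""Atom-level distance templating.

"Templating" a molecule means conditioning on its all-by-all pairwise
distances so a predictor recapitulates the conformation. The template is a
symmetric distance matrix over a selection of atoms with a boolean mask of
constrained pairs; adherence of a prediction is scored lDDT-style over the
masked pairs with the standard {0.5, 1, 2, 4} Angstrom thresholds, so a
ligand-only template score reads like a ligand-only lDDT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PipelineState

DEFAULT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
#: default network-ready distance bin edges (Angstrom)
DEFAULT_BIN_EDGES = tuple(np.arange(3.25, 50.75 + 1e-9, 1.25))


@dataclass
class DistanceTemplate:
    member_uids: list[int]
    distances: np.ndarray  # symmetric (n, n) Angstrom
    mask: np.ndarray       # boolean (n, n); True = constrained pair

    def validate(self) -> None:
        n = len(self.member_uids)
        assert self.distances.shape == (n, n) and self.mask.shape == (n, n)
        assert np.allclose(self.distances, self.distances.T)
        assert not self.mask.diagonal().any()
        assert np.array_equal(self.mask, self.mask.T)
        d = self.distances[self.mask]
        assert np.isfinite(d).all() and (d >= 0).all()

    def to_dict(self) -> dict:
        return {"member_uids": [int(u) for u in self.member_uids],
                "distances": self.distances.ravel().tolist(),
                "mask": self.mask.ravel().astype(int).tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "DistanceTemplate":
        n = len(d["member_uids"])
        return cls(list(d["member_uids"]),
                   np.asarray(d["distances"], float).reshape(n, n),
                   np.asarray(d["mask"], bool).reshape(n, n))


def build_distance_template(state: PipelineState, selection,
                            mode: str = "all_pairs",
                            pairs=None) -> DistanceTemplate:
    """Build a template over ``selection`` (atom uids) from current coords.

    ``all_pairs`` constrains every off-diagonal pair within the selection;
    ``explicit`` constrains only ``pairs`` (uid 2-tuples). Unresolved atoms
    in the selection are an error.
    """
    uids = [int(u) for u in selection]
    atoms = state.table.atoms.set_index("atom_uid")
    missing = [u for u in uids if u not in atoms.index]
    if missing:
        raise KeyError(f"selection references unknown atom_uid(s): {missing}")
    sub = atoms.loc[uids]
    xyz = sub[["x", "y", "z"]].to_numpy(float)
    bad = [u for u, ok in zip(uids, np.isfinite(xyz).all(axis=1)) if not ok]
    bad += [u for u, res in zip(uids, sub["is_resolved"]) if not res]
    if bad:
        raise ValueError(f"unresolved atoms in selection: {sorted(set(bad))}")
    diff = xyz[:, None, :] - xyz[None, :, :]
    distances = np.sqrt((diff ** 2).sum(-1))
    n = len(uids)
    if mode == "all_pairs":
        mask = ~np.eye(n, dtype=bool)
    elif mode == "explicit":
        if not pairs:
            raise ValueError("explicit mode requires a non-empty pair list")
        pos = {u: i for i, u in enumerate(uids)}
        mask = np.zeros((n, n), dtype=bool)
        for a, b in pairs:
            i, j = pos[int(a)], pos[int(b)]
            if i == j:
                raise ValueError("cannot constrain an atom against itself")
            mask[i, j] = mask[j, i] = True
    else:
        raise ValueError(f"unknown template mode {mode!r}")
    template = DistanceTemplate(uids, distances, mask)
    template.validate()
    return template


def bin_distances(template: DistanceTemplate, edges=DEFAULT_BIN_EDGES
                  ) -> np.ndarray:
    """One-hot discretization of masked distances over len(edges)+1 half-open
    bins [lo, hi); a distance exactly on an edge falls in the upper bin.
    Unmasked pairs are all-zero. Returns an (n, n, n_bins) array."""
    edges = np.asarray(edges, float)
    if edges.ndim != 1 or len(edges) == 0 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly ascending")
    n = len(template.member_uids)
    n_bins = len(edges) + 1
    out = np.zeros((n, n, n_bins))
    idx = np.searchsorted(edges, template.distances, side="right")
    ii, jj = np.nonzero(template.mask)
    out[ii, jj, idx[ii, jj]] = 1.0
    return out


def template_adherence(pred_state: PipelineState, template: DistanceTemplate,
                       thresholds=DEFAULT_THRESHOLDS) -> float:
    """lDDT-style adherence of a prediction to the template's masked pairs.

    Per pair: the fraction of thresholds within which the absolute deviation
    |d_pred - d_template| falls; returned as the mean over masked pairs.
    Exactly 1.0 iff every masked distance is reproduced within the smallest
    threshold. Invariant under rigid motion of the prediction."""
    if not template.mask.any():
        raise ValueError("template has no constrained pairs")
    xyz = pred_state.table.coords_by_uid(template.member_uids)
    if not np.isfinite(xyz).all():
        raise ValueError("prediction lacks coordinates for template atoms")
    diff = xyz[:, None, :] - xyz[None, :, :]
    d_pred = np.sqrt((diff ** 2).sum(-1))
    dev = np.abs(d_pred - template.distances)[template.mask]
    th = np.asarray(thresholds, float)
    scores = (dev[:, None] < th[None, :]).mean(axis=1)
    return float(scores.mean())
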