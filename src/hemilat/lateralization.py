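"""Laterality indices, network averages, the young-group template and alignment.

For a homotopic pair with left/right strength values L and R the laterality
index is

    LI = (L - R) / |L + R|

computed separately for the intrahemispheric (``li_intra``) and heterotopic
(``li_he``) strength sums. Positive LI means stronger left-hemisphere
involvement, negative means right. The denominator can vanish, so a pair is
marked invalid (NaN, flag false) when |L + R| falls below a small epsilon;
invalid pairs are excluded pairwise from network averages. Note |LI| can
exceed 1 when L and R have opposite signs — values are kept as computed.

Network-based LI averages pair LIs over homotopic pairs whose two members
carry the same (non-NONE) network label. "Alignment-to-young" is the cosine
similarity between a subject's vector of pair LIs in a network and the
young-group mean vector over the same pairs: it measures how similar the
subject's lateralization *pattern* is to the young template, independent of
overall magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas_io import NETWORKS, HomotopicAtlas
from .connectivity import StrengthSums
from .errors import ShapeError, UndefinedStatisticError

#: pairs with |L + R| below this are marked invalid rather than clipped
LI_EPSILON = 1e-8

LI_KINDS = ("intra", "he")


@dataclass(frozen=True)
class LIMap:
    """Per-pair laterality indices for one subject (or a group mean).

    ``table`` has one row per homotopic pair, sorted by pair_id, with columns
    pair_id, li_intra, li_he, valid_intra, valid_he. Invalid entries are NaN.
    """

    table: pd.DataFrame

    def values(self, kind: str) -> np.ndarray:
        return self.table[f"li_{kind}"].to_numpy(dtype=float)

    def valid(self, kind: str) -> np.ndarray:
        return self.table[f"valid_{kind}"].to_numpy(dtype=bool)

    @property
    def pair_ids(self) -> np.ndarray:
        return self.table["pair_id"].to_numpy()


def _li(numer_left: np.ndarray, right: np.ndarray, epsilon: float) -> tuple[np.ndarray, np.ndarray]:
    denom = np.abs(numer_left + right)
    valid = denom >= epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        li = (numer_left - right) / denom
    li = np.where(valid, li, np.nan)
    return li, valid


def pair_li(sums: StrengthSums, atlas: HomotopicAtlas, epsilon: float = LI_EPSILON) -> LIMap:
    """LI per homotopic pair from per-vertex strength sums."""
    if len(sums.he) != atlas.n_vertices or len(sums.intra) != atlas.n_vertices:
        raise ShapeError("strength sums do not cover the atlas")
    pairs = atlas.pairs()
    li_cols: dict[str, np.ndarray] = {"pair_id": pairs["pair_id"].to_numpy()}
    for kind, arr in (("intra", np.asarray(sums.intra)), ("he", np.asarray(sums.he))):
        left = arr[pairs["left_index"].to_numpy()]
        right = arr[pairs["right_index"].to_numpy()]
        li, valid = _li(left, right, epsilon)
        li_cols[f"li_{kind}"] = li
        li_cols[f"valid_{kind}"] = valid
    return LIMap(pd.DataFrame(li_cols))


def network_li(limap: LIMap, atlas: HomotopicAtlas) -> pd.DataFrame:
    """Mean LI per network over valid, network-valid pairs.

    Returns one row per network present in the atlas with columns
    network, li_intra, li_he, n_pairs_intra, n_pairs_he. A network whose
    pairs are all invalid gets NaN with a zero count.
    """
    pairs = atlas.pairs()
    merged = pairs.merge(limap.table, on="pair_id", validate="one_to_one")
    rows = []
    for net in NETWORKS:
        sel = merged[(merged["network_left"] == net) & merged["network_valid"]]
        if sel.empty:
            continue
        row: dict[str, object] = {"network": net}
        for kind in LI_KINDS:
            vals = sel.loc[sel[f"valid_{kind}"], f"li_{kind}"]
            row[f"li_{kind}"] = float(vals.mean()) if len(vals) else math.nan
            row[f"n_pairs_{kind}"] = int(len(vals))
        rows.append(row)
    return pd.DataFrame(rows)


def young_template(limaps: list[LIMap], atlas: HomotopicAtlas) -> dict[str, dict[str, pd.Series]]:
    """Young-group mean LI per pair, restricted to network-valid pairs.

    A pair enters the template only if it is valid in *every* young subject
    (listwise within network), so all alignment comparisons for a network use
    one fixed index set. Returns ``template[kind][network]`` as a Series of
    mean LI indexed by pair_id.
    """
    if not limaps:
        raise ValueError("young template needs at least one subject")
    pairs = atlas.pairs()
    base = limaps[0].table["pair_id"]
    for m in limaps[1:]:
        if not base.equals(m.table["pair_id"]):
            raise ShapeError("LI maps index different pair sets")
    out: dict[str, dict[str, pd.Series]] = {}
    for kind in LI_KINDS:
        vals = np.stack([m.values(kind) for m in limaps])
        valid_all = np.all(np.stack([m.valid(kind) for m in limaps]), axis=0)
        mean = vals.mean(axis=0)
        per_net: dict[str, pd.Series] = {}
        for net in NETWORKS:
            net_mask = ((pairs["network_left"] == net) & pairs["network_valid"]).to_numpy()
            keep = net_mask & valid_all
            if keep.any():
                per_net[net] = pd.Series(mean[keep], index=base.to_numpy()[keep])
        out[kind] = per_net
    return out


def alignment(limap: LIMap, template: dict[str, dict[str, pd.Series]], network: str, kind: str) -> float:
    """Cosine similarity between a subject's pair-LI vector and the young template.

    Computed over the template's pair set intersected with the subject's valid
    pairs; needs at least 2 shared pairs and nonzero norms.
    """
    tmpl = template[kind].get(network)
    if tmpl is None:
        raise UndefinedStatisticError(f"no template for network {network!r}")
    subj = pd.Series(limap.values(kind), index=limap.pair_ids)[limap.valid(kind)]
    shared = tmpl.index.intersection(subj.index)
    if len(shared) < 2:
        raise UndefinedStatisticError(
            f"fewer than 2 shared valid pairs in {network} ({len(shared)})"
        )
    u = subj.loc[shared].to_numpy()
    v = tmpl.loc[shared].to_numpy()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UndefinedStatisticError(f"zero-norm LI vector in {network}")
    return float(np.dot(u, v) / (nu * nv))


def group_mean_map(limaps: list[LIMap]) -> LIMap:
    """Per-pair mean LI over the subjects in which the pair is valid."""
    if not limaps:
        raise ValueError("group mean needs at least one subject")
    base = limaps[0].table["pair_id"]
    cols: dict[str, np.ndarray] = {"pair_id": base.to_numpy()}
    for kind in LI_KINDS:
        vals = np.stack([m.values(kind) for m in limaps])
        valid = np.stack([m.valid(kind) for m in limaps])
        counts = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, np.nansum(np.where(valid, vals, 0.0), axis=0) / np.maximum(counts, 1), np.nan)
        cols[f"li_{kind}"] = mean
        cols[f"valid_{kind}"] = counts > 0
        cols[f"n_valid_{kind}"] = counts
    return LIMap(pd.DataFrame(cols))


def map_correlation(map_a: LIMap, map_b: LIMap, kind: str) -> float:
    """Pearson r between two LI maps over their shared valid pairs."""
    a = pd.Series(map_a.values(kind), index=map_a.pair_ids)[map_a.valid(kind)]
    b = pd.Series(map_b.values(kind), index=map_b.pair_ids)[map_b.valid(kind)]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise UndefinedStatisticError("map correlation needs at least 3 shared valid pairs")
    x, y = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("map correlation undefined for a constant map")
    return float(stats.pearsonr(x, y).statistic)


def compare_dependent_correlations(r1: float, r2: float, r12: float, n: int) -> float:
    """Steiger's z for two correlations sharing one variable.

    ``r1`` = corr(x, y1), ``r2`` = corr(x, y2), ``r12`` = corr(y1, y2) on the
    same n observations. Uses the back-transformed mean correlation in the
    pooled determinant term. Positive z means r1 > r2.
    """
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if not -1 < r < 1:
            raise ValueError(f"{name} must lie strictly inside (-1, 1), got {r}")
    if n < 4:
        raise ValueError("need n >= 4")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar = float(np.tanh((z1 + z2) / 2.0))
    f = (1.0 - r12) / (2.0 * (1.0 - rbar**2))
    h = (1.0 - f * rbar**2) / (1.0 - rbar**2)
    return float((z1 - z2) * math.sqrt((n - 3) / (2.0 * (1.0 - r12) * h)))
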