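"""Synthetic cohorts with planted hemispheric lateralization.

The generator emulates the study conditions end to end: a bilateral vertex
atlas with an exact homotopic bijection and seven network labels, per-subject
multivariate-normal BOLD-like time series whose covariance carries
group-specific coupling asymmetries, framewise-displacement traces, and a
subject table whose covariates match the published group summaries, with
behavior optionally linked to each subject's realized laterality.

The covariance is a latent-factor model: for each network one "intra" factor
per hemisphere (loading sqrt(intra_H) on that hemisphere's network vertices),
one cross-hemisphere "hetero" factor (loading sqrt(hetero_L) on left and
sqrt(hetero_R) on right network vertices), one homotopic factor per vertex
pair (loading sqrt(homotopic) on both members), plus independent noise of
variance noise_sd^2. Covariance = W W^T + D is positive semidefinite by
construction for any nonnegative weights, and expected Pearson correlations
follow in closed form from the loadings:

    var            = intra_H + hetero_H + homotopic + noise_sd^2
    cov within-H   = intra_H + hetero_H           (same network, same hemi)
    cov cross      = sqrt(hetero_L * hetero_R)    (same network, non-partner)
    cov homotopic  = sqrt(hetero_L * hetero_R) + homotopic

An intra_L > intra_R asymmetry therefore raises within-left correlations and
plants a positive LI_intra in that network. The cross-hemisphere covariance
block is symmetric under this construction, so heterotopic strength sums are
balanced in expectation; LI_he is exercised as a null measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas_io import (
    NETWORK_TOKENS,
    NETWORKS,
    CohortTable,
    HomotopicAtlas,
    TimeSeries,
    write_atlas,
    write_cohort,
    write_fd,
    write_timeseries,
)
from .connectivity import compute_fc, mean_global_fc, strength_sums
from .errors import NumericError
from .lateralization import network_li, pair_li

DEFAULT_SEED = 20240605
DEFAULT_N_TIMEPOINTS = 750
DEFAULT_PAIRS_PER_NETWORK: dict[str, int] = {**{n: 120 for n in NETWORKS}, "NONE": 48}
DEFAULT_GROUP_SIZES: dict[str, int] = {"YNM": 24, "OM": 23, "ONM": 23}
#: fraction of female subjects per group (12/24, 9/23, 14/23)
DEFAULT_FEMALE_COUNTS: dict[str, int] = {"YNM": 12, "OM": 9, "ONM": 14}
#: fraction of frames above the 0.5 mm censoring threshold, per group
DEFAULT_OUTLIER_FRACTIONS: dict[str, float] = {"YNM": 0.01, "OM": 0.02, "ONM": 0.04}

#: eigenvalues of a covariance may dip this far below zero before it is rejected
PSD_TOLERANCE = -1e-8


@dataclass(frozen=True)
class NetworkCoupling:
    """Factor loadings (squared-weight scale) for one network."""

    intra_L: float = 0.2
    intra_R: float = 0.2
    hetero_L: float = 0.1
    hetero_R: float = 0.1
    homotopic: float = 0.25
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("intra_L", "intra_R", "hetero_L", "hetero_R", "homotopic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def symmetric(self) -> bool:
        return self.intra_L == self.intra_R and self.hetero_L == self.hetero_R


@dataclass(frozen=True)
class LateralizationPlan:
    """Per-network coupling weights for one group's generative covariance.

    ``global_coupling`` adds one whole-brain factor loading sqrt(g) on every
    vertex — the positive background FC real cortex shows. It keeps
    whole-hemisphere strength sums bounded away from zero, so the LI ratio
    (L-R)/|L+R| is well-conditioned; without it small synthetic atlases
    produce near-zero denominators and heavy-tailed LI maps.
    """

    couplings: Mapping[str, NetworkCoupling]
    global_coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.global_coupling < 0:
            raise ValueError("global_coupling must be nonnegative")
        bad = set(self.couplings) - set(NETWORK_TOKENS)
        if bad:
            raise ValueError(f"unknown network(s) in plan: {sorted(bad)}")
        object.__setattr__(self, "couplings", dict(self.couplings))

    @classmethod
    def uniform(
        cls,
        coupling: NetworkCoupling | None = None,
        networks: tuple[str, ...] = NETWORK_TOKENS,
        global_coupling: float = 0.0,
    ) -> "LateralizationPlan":
        c = coupling if coupling is not None else NetworkCoupling()
        return cls({n: c for n in networks}, global_coupling)

    def with_network(self, network: str, coupling: NetworkCoupling) -> "LateralizationPlan":
        d = dict(self.couplings)
        d[network] = coupling
        return LateralizationPlan(d, self.global_coupling)

    def swapped(self) -> "LateralizationPlan":
        """The hemisphere-mirrored plan (L and R weights exchanged)."""
        return LateralizationPlan(
            {
                n: replace(c, intra_L=c.intra_R, intra_R=c.intra_L, hetero_L=c.hetero_R, hetero_R=c.hetero_L)
                for n, c in self.couplings.items()
            },
            self.global_coupling,
        )


def young_plan() -> LateralizationPlan:
    """Default young-group plan: right-lateralized CON, mildly left-lateralized LAN/DMN.

    Magnitudes are calibration choices producing realistic within-network
    correlations (~0.2-0.4) over a positive global FC background; see the
    methods note.
    """
    base = LateralizationPlan.uniform(global_coupling=0.12)
    base = base.with_network("CON", NetworkCoupling(intra_L=0.10, intra_R=0.30))
    base = base.with_network("LAN", NetworkCoupling(intra_L=0.28, intra_R=0.16))
    base = base.with_network("DMN", NetworkCoupling(intra_L=0.26, intra_R=0.18))
    base = base.with_network("NONE", NetworkCoupling(intra_L=0.15, intra_R=0.15, hetero_L=0.08, hetero_R=0.08, homotopic=0.2))
    return base


def older_nonmusician_plan() -> LateralizationPlan:
    """Reduced-asymmetry plan: the young asymmetries shrunk toward symmetry."""
    return _shrink_asymmetry(young_plan(), factor=0.25)


def older_musician_plan() -> LateralizationPlan:
    """Preserved (youth-like) plan for the older musician group."""
    return _shrink_asymmetry(young_plan(), factor=0.9)


def _shrink_asymmetry(plan: LateralizationPlan, factor: float) -> LateralizationPlan:
    out = {}
    for n, c in plan.couplings.items():
        mi = (c.intra_L + c.intra_R) / 2
        mh = (c.hetero_L + c.hetero_R) / 2
        out[n] = replace(
            c,
            intra_L=mi + factor * (c.intra_L - mi),
            intra_R=mi + factor * (c.intra_R - mi),
            hetero_L=mh + factor * (c.hetero_L - mh),
            hetero_R=mh + factor * (c.hetero_R - mh),
        )
    return LateralizationPlan(out, plan.global_coupling)


def default_plans() -> dict[str, LateralizationPlan]:
    return {"YNM": young_plan(), "OM": older_musician_plan(), "ONM": older_nonmusician_plan()}


@dataclass(frozen=True)
class BehaviorLinkSpec:
    """Linear-Gaussian link from a subject's realized network LI to behavior.

    behavior = group mean + slope * LI(network, kind)
             + sum(covariate_effects[c] * covariate_c) + N(0, noise_sd).
    """

    behavior: str = "sin"  # "sin" or "sis"
    network: str = "DAN"
    kind: str = "intra"
    slope: float = 0.0  # dB per LI unit
    noise_sd: float = 1.5  # dB
    covariate_effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.behavior not in ("sin", "sis"):
            raise ValueError("link behavior must be 'sin' or 'sis'")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        object.__setattr__(self, "covariate_effects", dict(self.covariate_effects))


# ---------------------------------------------------------------------------
# atlas


def make_atlas(
    pairs_per_network: Mapping[str, int] | None = None, seed: int = DEFAULT_SEED
) -> HomotopicAtlas:
    """Random bilateral atlas with an exact homotopic bijection.

    Both members of every pair share the network label. Vertex row order is a
    seeded permutation so hemisphere/network structure is not block-contiguous;
    vertex_id equals row position (0-based).
    """
    counts = dict(pairs_per_network) if pairs_per_network is not None else dict(DEFAULT_PAIRS_PER_NETWORK)
    if not counts:
        raise ValueError("need at least one network")
    bad = set(counts) - set(NETWORK_TOKENS)
    if bad:
        raise ValueError(f"unknown network(s): {sorted(bad)}")
    if any(c < 1 for c in counts.values()):
        raise ValueError("every pair count must be >= 1")
    hemi, pid, net = [], [], []
    p = 0
    for network in counts:
        for _ in range(counts[network]):
            hemi += ["L", "R"]
            pid += [p, p]
            net += [network, network]
            p += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pid))
    return HomotopicAtlas(
        vertex_id=np.arange(len(pid)),
        hemisphere=np.array(hemi, dtype=object)[order],
        pair_id=np.array(pid)[order],
        network=np.array(net, dtype=object)[order],
    )


# ---------------------------------------------------------------------------
# covariance and sampling


def build_covariance(atlas: HomotopicAtlas, plan: LateralizationPlan) -> np.ndarray:
    """Latent-factor covariance for one group (see module docstring)."""
    present = set(atlas.network)
    missing = present - set(plan.couplings)
    if missing:
        raise ValueError(f"plan missing network(s): {sorted(missing)}")
    n = atlas.n_vertices
    left = atlas.left_mask
    blocks: list[np.ndarray] = []
    noise_var = np.zeros(n)
    for network in sorted(present):
        c = plan.couplings[network]
        in_net = atlas.network == network
        col_intra_l = np.where(in_net & left, np.sqrt(c.intra_L), 0.0)
        col_intra_r = np.where(in_net & ~left, np.sqrt(c.intra_R), 0.0)
        col_hetero = np.where(in_net & left, np.sqrt(c.hetero_L), 0.0) + np.where(
            in_net & ~left, np.sqrt(c.hetero_R), 0.0
        )
        blocks.append(np.column_stack([col_intra_l, col_intra_r, col_hetero]))
        noise_var[in_net] = c.noise_sd**2
    # one homotopic factor per pair
    pairs = atlas.pairs()
    homo = np.zeros((n, atlas.n_pairs))
    for j, (li, ri) in enumerate(zip(pairs["left_index"], pairs["right_index"])):
        w = np.sqrt(plan.couplings[str(atlas.network[li])].homotopic)
        homo[li, j] = w
        homo[ri, j] = w
    if plan.global_coupling > 0:
        blocks.append(np.full((n, 1), np.sqrt(plan.global_coupling)))
    w_mat = np.column_stack(blocks + [homo])
    cov = w_mat @ w_mat.T
    cov[np.diag_indices(n)] += noise_var
    return cov


def expected_correlations(plan: LateralizationPlan) -> pd.DataFrame:
    """Closed-form expected Pearson correlations per network.

    Columns: within_L, within_R (same network & hemisphere), cross (same
    network, opposite hemispheres, non-partner) and homotopic.
    """
    rows = []
    g = plan.global_coupling
    for network, c in plan.couplings.items():
        var_l = c.intra_L + c.hetero_L + c.homotopic + g + c.noise_sd**2
        var_r = c.intra_R + c.hetero_R + c.homotopic + g + c.noise_sd**2
        cross_cov = np.sqrt(c.hetero_L * c.hetero_R) + g
        rows.append(
            {
                "network": network,
                "within_L": (c.intra_L + c.hetero_L + g) / var_l,
                "within_R": (c.intra_R + c.hetero_R + g) / var_r,
                "cross": cross_cov / np.sqrt(var_l * var_r),
                "homotopic": (cross_cov + c.homotopic) / np.sqrt(var_l * var_r),
            }
        )
    return pd.DataFrame(rows).set_index("network")


class MVNSampler:
    """Zero-mean multivariate-normal sampler with a cached factorization."""

    def __init__(self, cov: np.ndarray):
        cov = np.asarray(cov, dtype=float)
        if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
            raise NumericError("covariance must be square")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise NumericError("covariance must be symmetric")
        w, v = np.linalg.eigh(cov)
        if w.min() < PSD_TOLERANCE:
            raise NumericError(f"covariance is not positive semidefinite (min eigenvalue {w.min():.3g})")
        self._transform = v * np.sqrt(np.clip(w, 0.0, None))
        self.n = cov.shape[0]

    def sample(self, n_timepoints: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((self.n, n_timepoints))
        return self._transform @ z


def simulate_timeseries(
    cov: np.ndarray,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    seed: int = DEFAULT_SEED,
    subject_id: str = "sim",
) -> TimeSeries:
    """Draw one subject's vertex x time matrix from N(0, cov), deterministically."""
    sampler = MVNSampler(cov)
    rng = np.random.default_rng(seed)
    return TimeSeries(subject_id, sampler.sample(n_timepoints, rng))


def simulate_fd(n_timepoints: int, outlier_fraction: float, seed: int = DEFAULT_SEED) -> np.ndarray:
    """FD trace (mm/frame) with exactly floor(fraction * n) frames above 0.5 mm."""
    if not 0.0 <= outlier_fraction <= 1.0:
        raise ValueError("outlier_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_out = int(np.floor(outlier_fraction * n_timepoints))
    fd = rng.uniform(0.02, 0.45, size=n_timepoints)
    if n_out:
        where = rng.choice(n_timepoints, size=n_out, replace=False)
        fd[where] = rng.uniform(0.55, 1.5, size=n_out)
    return fd


# ---------------------------------------------------------------------------
# cohort

#: Per-group covariate generating parameters (mean, SD) — the study conditions.
COVARIATE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "YNM": {
        "age": (23.13, 2.38), "education": (16.50, 1.67), "hearing": (0.71, 3.32),
        "digit_span": (16.71, 2.71), "stroop": (0.18, 0.12),
        "sin": (-3.99, 0.59), "sis": (-5.43, 1.00),
    },
    "OM": {
        "age": (64.61, 3.76), "education": (13.15, 3.06), "hearing": (12.33, 5.42),
        "moca": (27.91, 1.24), "digit_span": (15.09, 2.27), "stroop": (0.18, 0.10),
        "sin": (-3.61, 0.97), "sis": (-4.97, 1.51),
        "training_onset": (11.17, 4.66), "training_years": (49.84, 8.26),
    },
    "ONM": {
        "age": (66.70, 3.34), "education": (9.89, 2.80), "hearing": (12.57, 4.01),
        "moca": (27.65, 1.37), "digit_span": (11.57, 2.06), "stroop": (0.23, 0.19),
        "sin": (-1.04, 1.90), "sis": (-0.31, 3.09),
    },
}


@dataclass
class SyntheticCohort:
    """Everything make_cohort generated for one replicate."""

    atlas: HomotopicAtlas
    cohort: CohortTable
    timeseries: dict[str, TimeSeries]
    fd: dict[str, np.ndarray]
    #: per subject x network LI table realized during generation
    network_li: pd.DataFrame


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def make_cohort(
    group_sizes: Mapping[str, int] | None = None,
    plans: Mapping[str, LateralizationPlan] | None = None,
    link: BehaviorLinkSpec | None = None,
    seed: int = DEFAULT_SEED,
    atlas: HomotopicAtlas | None = None,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    outlier_fractions: Mapping[str, float] | None = None,
) -> SyntheticCohort:
    """Generate a full synthetic cohort: atlas, time series, FD traces, subject table.

    Covariates are drawn from independent truncated normals matching the
    per-group study summaries; female/male counts are fixed at 12/12, 9/14 and
    14/9 for the default sizes (scaled proportionally otherwise). mFD and mean
    global FC are the *realized* values of each subject's generated FD trace
    and connectivity matrix. Behavior is the group mean plus, when a link is
    given, a linear function of the subject's realized network LI, covariate
    effects, and Gaussian noise.
    """
    sizes = dict(group_sizes) if group_sizes is not None else dict(DEFAULT_GROUP_SIZES)
    for g, n in sizes.items():
        if g not in COVARIATE_PARAMS:
            raise ValueError(f"unknown group {g!r}")
        if n < 2:
            raise ValueError("every group size must be >= 2")
    plans = dict(plans) if plans is not None else default_plans()
    fractions = dict(outlier_fractions) if outlier_fractions is not None else dict(DEFAULT_OUTLIER_FRACTIONS)
    if atlas is None:
        atlas = make_atlas(seed=seed)
    samplers = {g: MVNSampler(build_covariance(atlas, plans[g])) for g in sizes}
    root = np.random.default_rng(seed)

    rows: list[dict] = []
    li_rows: list[pd.DataFrame] = []
    timeseries: dict[str, TimeSeries] = {}
    fd_traces: dict[str, np.ndarray] = {}
    for group in sizes:
        n_female = DEFAULT_FEMALE_COUNTS.get(group, 0)
        default_n = DEFAULT_GROUP_SIZES.get(group, sizes[group])
        n_f = int(round(sizes[group] * n_female / default_n)) if default_n else 0
        params = COVARIATE_PARAMS[group]
        for i in range(sizes[group]):
            sid = f"{group}{i + 1:03d}"
            ts = TimeSeries(sid, samplers[group].sample(n_timepoints, root))
            fd = simulate_fd(n_timepoints, fractions.get(group, 0.02), seed=int(root.integers(2**31)))
            fc = compute_fc(ts, fd)
            sums = strength_sums(fc, atlas)
            limap = pair_li(sums, atlas)
            nli = network_li(limap, atlas)
            nli.insert(0, "subject_id", sid)
            nli.insert(1, "group", group)
            li_rows.append(nli)
            row: dict[str, object] = {
                "subject_id": sid,
                "group": group,
                "gender": "F" if i < n_f else "M",
                "age": _truncated_normal(root, *params["age"], 18.0, 90.0),
                "education": _truncated_normal(root, *params["education"], 0.0, 25.0),
                "hearing": _truncated_normal(root, *params["hearing"], -10.0, 40.0),
                "moca": (
                    round(_truncated_normal(root, *params["moca"], 20.0, 30.0))
                    if "moca" in params else np.nan
                ),
                "digit_span": round(_truncated_normal(root, *params["digit_span"], 3.0, 22.0)),
                "stroop": _truncated_normal(root, *params["stroop"], 0.01, 2.0),
                "mfd": float(fd.mean()),
                "mean_global_fc": mean_global_fc(fc),
                "training_onset": (
                    _truncated_normal(root, *params["training_onset"], 3.0, 23.0)
                    if "training_onset" in params else np.nan
                ),
                "training_years": (
                    _truncated_normal(root, *params["training_years"], 32.0, 80.0)
                    if "training_years" in params else np.nan
                ),
            }
            for behavior in ("sin", "sis"):
                mean, sd = params[behavior]
                if link is not None and link.behavior == behavior:
                    sel = nli[nli["network"] == link.network]
                    li_val = float(sel[f"li_{link.kind}"].iloc[0]) if len(sel) else 0.0
                    value = mean + link.slope * li_val + root.normal(0.0, link.noise_sd)
                    for cov_name, eff in link.covariate_effects.items():
                        value += eff * float(row[cov_name])
                else:
                    value = root.normal(mean, sd)
                row[f"{behavior}_threshold"] = float(value)
            rows.append(row)
            timeseries[sid] = ts
            fd_traces[sid] = fd
    cohort = CohortTable(pd.DataFrame(rows))
    return SyntheticCohort(
        atlas=atlas,
        cohort=cohort,
        timeseries=timeseries,
        fd=fd_traces,
        network_li=pd.concat(li_rows, ignore_index=True),
    )


def write_dataset(data: SyntheticCohort, out_dir: str | Path, dialect: str = "text") -> None:
    """Write atlas.tsv, cohort.tsv and per-subject time-series + FD files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_atlas(data.atlas, out / "atlas.tsv")
    write_cohort(data.cohort, out / "cohort.tsv")
    ext = "tsv" if dialect == "text" else "bin"
    for sid, ts in data.timeseries.items():
        write_timeseries(ts, out / f"{sid}.ts.{ext}", dialect=dialect)
        write_fd(data.fd[sid], out / f"{sid}.fd.tsv")
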