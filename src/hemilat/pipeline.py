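"""End-to-end orchestration: simulate -> QC -> FC -> LI -> alignment -> statistics.

A run is fully described by a :class:`RunConfig` (YAML- or dict-loadable) and
is deterministic given its seeds. Outputs are plain text: ``network_li.tsv``,
``alignment.tsv``, ``qc_report.tsv``, ``results_stats.json`` and
``run_report.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas_io import (
    GROUPS,
    NETWORKS,
    CohortTable,
    HomotopicAtlas,
    load_atlas,
    load_cohort,
    load_fd,
    load_timeseries,
)
from .connectivity import (
    FD_THRESHOLD_MM,
    MAX_OUTLIER_FRACTION,
    compute_fc,
    mean_global_fc,
    motion_qc,
    strength_sums,
)
from .errors import HemilatError, UndefinedStatisticError
from .group_stats import (
    StatResult,
    chi_square_independence,
    fdr_bh,
    games_howell,
    jonckheere_terpstra,
    one_sample_t,
    oneway_anova,
    pairwise_t_fdr,
    partial_correlation,
    two_sample_t,
)
from .lateralization import (
    LI_EPSILON,
    LI_KINDS,
    LIMap,
    alignment,
    compare_dependent_correlations,
    group_mean_map,
    map_correlation,
    network_li,
    pair_li,
    young_template,
)
from .synthetic import BehaviorLinkSpec, default_plans, make_atlas, make_cohort

log = logging.getLogger("hemilat")

#: covariates regressed out of the LI/alignment-behavior partial correlations
DEFAULT_COVARIATES = (
    "age",
    "gender",
    "education",
    "hearing",
    "moca",
    "digit_span",
    "stroop",
    "mfd",
    "mean_global_fc",
)


@dataclass
class RunConfig:
    """Everything a full run needs; see module docstring."""

    out_dir: str = "hemilat_out"
    # either simulate ...
    simulate: bool = True
    seed: int = 20240605
    group_sizes: dict = field(default_factory=lambda: {"YNM": 24, "OM": 23, "ONM": 23})
    n_timepoints: int = 750
    pairs_per_network: dict | None = None
    link: dict | None = None
    # ... or read files
    atlas_path: str | None = None
    cohort_path: str | None = None
    timeseries_dir: str | None = None
    # thresholds
    fd_threshold: float = FD_THRESHOLD_MM
    max_outlier_fraction: float = MAX_OUTLIER_FRACTION
    li_epsilon: float = LI_EPSILON
    heterogeneity_alpha: float = 0.05
    fdr_alpha: float = 0.05
    scrub: bool = True
    template_mode: str = "include_self"  # or "leave_one_out"
    jt_direction: str = "decreasing"
    covariates: tuple = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        for name in ("max_outlier_fraction", "heterogeneity_alpha", "fdr_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.template_mode not in ("include_self", "leave_one_out"):
            raise ValueError(f"unknown template_mode {self.template_mode!r}")
        if self.jt_direction not in ("increasing", "decreasing"):
            raise ValueError(f"unknown jt_direction {self.jt_direction!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    version: str
    n_subjects_in: int
    excluded: list
    stage_counts: dict
    warnings: list


def _stat_record(name: str, res: StatResult, **labels) -> dict:
    rec = {"name": name, **labels, **res.to_dict()}
    return rec


def _present_groups(cohort: CohortTable) -> list[str]:
    present = set(cohort.table["group"])
    return [g for g in GROUPS if g in present]


def compute_subject_measures(
    atlas: HomotopicAtlas,
    timeseries: dict,
    fd: dict,
    config: RunConfig,
) -> tuple[dict[str, LIMap], pd.DataFrame, pd.DataFrame, list[dict]]:
    """QC + FC + strength sums + LI for every subject.

    Returns (limaps, per-subject network-LI table, QC table, exclusions).
    """
    limaps: dict[str, LIMap] = {}
    nli_rows, qc_rows, excluded = [], [], []
    for sid, ts in timeseries.items():
        trace = fd.get(sid)
        if trace is not None:
            qc = motion_qc(trace, sid, config.fd_threshold, config.max_outlier_fraction)
            qc_rows.append(asdict(qc))
            if qc.excluded:
                excluded.append({"subject_id": sid, "reason": f"outlier fraction {qc.outlier_fraction:.3f} > {config.max_outlier_fraction}"})
                continue
        fc = compute_fc(ts, trace, censor=config.scrub, fd_threshold=config.fd_threshold)
        sums = strength_sums(fc, atlas)
        limap = pair_li(sums, atlas, epsilon=config.li_epsilon)
        limaps[sid] = limap
        nli = network_li(limap, atlas)
        nli.insert(0, "subject_id", sid)
        nli["mean_global_fc"] = mean_global_fc(fc)
        nli_rows.append(nli)
    nli_table = pd.concat(nli_rows, ignore_index=True) if nli_rows else pd.DataFrame()
    qc_table = pd.DataFrame(qc_rows)
    return limaps, nli_table, qc_table, excluded


def compute_alignment(
    limaps: dict[str, LIMap],
    atlas: HomotopicAtlas,
    cohort: CohortTable,
    mode: str = "include_self",
) -> tuple[pd.DataFrame, list[dict]]:
    """Alignment-to-young per subject x network x LI kind."""
    young_ids = [s for s in cohort.subjects("YNM") if s in limaps]
    if not young_ids:
        raise HemilatError("alignment requires at least one YNM subject with usable data")
    template_all = young_template([limaps[s] for s in young_ids], atlas)
    rows, warnings = [], []
    for sid, limap in limaps.items():
        group = cohort.table.set_index("subject_id").loc[sid, "group"]
        if mode == "leave_one_out" and sid in young_ids and len(young_ids) > 2:
            tmpl = young_template([limaps[s] for s in young_ids if s != sid], atlas)
        else:
            tmpl = template_all
        for kind in LI_KINDS:
            for net in NETWORKS:
                try:
                    value = alignment(limap, tmpl, net, kind)
                except UndefinedStatisticError as exc:
                    warnings.append({"subject_id": sid, "network": net, "kind": kind, "warning": str(exc)})
                    continue
                rows.append(
                    {"subject_id": sid, "group": group, "network": net, "kind": kind, "alignment": value}
                )
    return pd.DataFrame(rows), warnings


def run_table1(cohort: CohortTable) -> list[dict]:
    """The demographic/behavioral battery on a raw cohort table.

    Chi-square on gender across groups; two-sample t (OM vs ONM) on age,
    education, MoCA and hearing; one-way ANOVA (Levene-gated classic/Welch)
    on SIN, SIS, digit span and Stroop across the three groups.
    """
    t = cohort.table
    order = _present_groups(cohort)
    if len(order) < 3:
        raise ValueError("the demographic battery requires all three groups")
    records = []
    counts = np.array(
        [[int(((t["group"] == g) & (t["gender"] == s)).sum()) for s in ("F", "M")] for g in order]
    )
    records.append(_stat_record("gender", chi_square_independence(counts), test="chi2"))
    om = t[t["group"] == "OM"]
    onm = t[t["group"] == "ONM"]
    for var in ("age", "education", "moca", "hearing"):
        a, b = om[var].dropna().to_numpy(float), onm[var].dropna().to_numpy(float)
        records.append(_stat_record(var, two_sample_t(a, b, "pooled"), test="t2", contrast="OM-ONM"))
    for var in ("sin_threshold", "sis_threshold", "digit_span", "stroop"):
        groups = [t.loc[t["group"] == g, var].to_numpy(float) for g in order]
        records.append(_stat_record(var, oneway_anova(groups, force="auto"), test="anova"))
    return records


def _anova_battery(
    values: pd.DataFrame, value_col: str, cohort: CohortTable, jt_direction: str | None
) -> list[dict]:
    """Per network x kind: one-sample t per group, omnibus ANOVA (+post hoc), optional JT.

    BH-FDR is applied within each family of seven network tests (per kind and
    test type); adjusted p lands in ``extra['p_fdr']`` of each record.
    """
    order = _present_groups(cohort)
    grp = cohort.table.set_index("subject_id")["group"]
    records: list[dict] = []
    for kind in sorted(values["kind"].unique()):
        sub = values[values["kind"] == kind]
        # one-sample t families: one per group
        for g in order:
            fam = []
            for net in NETWORKS:
                v = sub[(sub["network"] == net) & (sub["subject_id"].map(grp) == g)][value_col]
                if len(v) >= 2 and v.std() > 0:
                    fam.append((net, one_sample_t(v.to_numpy(float))))
            adj = fdr_bh(np.array([r.p for _, r in fam])) if fam else []
            for (net, res), pa in zip(fam, adj):
                res.extra["p_fdr"] = float(pa)
                records.append(_stat_record(value_col, res, test="one_sample_t", kind=kind, network=net, group=g))
        # omnibus family across groups
        fam_om: list[tuple[str, StatResult, list[StatResult]]] = []
        jt_fam: list[tuple[str, StatResult]] = []
        for net in NETWORKS:
            groups = []
            for g in order:
                v = sub[(sub["network"] == net) & (sub["subject_id"].map(grp) == g)][value_col]
                groups.append(v.to_numpy(float))
            if any(len(g) < 2 for g in groups):
                continue
            omnibus = oneway_anova(groups, force="auto")
            post = (
                games_howell(groups, order)
                if omnibus.method == "welch_f"
                else pairwise_t_fdr(groups, order)
            )
            fam_om.append((net, omnibus, post))
            if jt_direction is not None and len(groups) >= 3:
                jt_fam.append((net, jonckheere_terpstra(groups, jt_direction)))
        adj = fdr_bh(np.array([r.p for _, r, _ in fam_om])) if fam_om else []
        for (net, res, post), pa in zip(fam_om, adj):
            res.extra["p_fdr"] = float(pa)
            records.append(_stat_record(value_col, res, test="anova", kind=kind, network=net))
            for pr in post:
                records.append(_stat_record(value_col, pr, test="posthoc", kind=kind, network=net))
        adj = fdr_bh(np.array([r.p for _, r in jt_fam])) if jt_fam else []
        for (net, res), pa in zip(jt_fam, adj):
            res.extra["p_fdr"] = float(pa)
            records.append(_stat_record(value_col, res, test="jt", kind=kind, network=net))
    return records


def _behavior_correlations(
    values: pd.DataFrame, value_col: str, cohort: CohortTable, covariates: tuple
) -> list[dict]:
    """Partial correlations of LI/alignment with SIN/SIS within each older group."""
    t = cohort.table.set_index("subject_id")
    records = []
    for g in ("OM", "ONM"):
        ids = [s for s in cohort.subjects(g) if s in set(values["subject_id"])]
        if not ids:
            continue
        sub_t = t.loc[ids]
        cov_cols = []
        for c in covariates:
            col = (sub_t["gender"] == "M").astype(float) if c == "gender" else sub_t[c].astype(float)
            cov_cols.append(col.to_numpy())
        cov = np.column_stack(cov_cols) if cov_cols else None
        for kind in sorted(values["kind"].unique()):
            for net in NETWORKS:
                sel = values[(values["kind"] == kind) & (values["network"] == net)]
                sel = sel.set_index("subject_id").reindex(ids)
                x = sel[value_col].to_numpy(float)
                if np.isnan(x).any():
                    continue
                for behavior in ("sin_threshold", "sis_threshold"):
                    y = sub_t[behavior].to_numpy(float)
                    n_cov = 0 if cov is None else cov.shape[1]
                    if len(ids) <= n_cov + 2:
                        continue
                    res = partial_correlation(x, y, cov)
                    records.append(
                        _stat_record(value_col, res, test="partial_corr", kind=kind, network=net, group=g, behavior=behavior)
                    )
    return records


def _map_comparisons(limaps: dict[str, LIMap], cohort: CohortTable) -> list[dict]:
    """Group-mean LI maps: YNM-vs-older correlations and their Steiger comparison."""
    grp = cohort.table.set_index("subject_id")["group"]
    by_group = {g: [m for s, m in limaps.items() if grp.get(s) == g] for g in GROUPS}
    if not all(by_group.get(g) for g in GROUPS):
        return []
    means = {g: group_mean_map(ms) for g, ms in by_group.items()}
    records = []
    for kind in LI_KINDS:
        try:
            r_onm = map_correlation(means["YNM"], means["ONM"], kind)
            r_om = map_correlation(means["YNM"], means["OM"], kind)
            r_older = map_correlation(means["OM"], means["ONM"], kind)
        except UndefinedStatisticError:
            continue
        n = int(min(means[g].valid(kind).sum() for g in GROUPS))
        z = compare_dependent_correlations(r_om, r_onm, r_older, n)
        records.append(
            {
                "name": "group_map_correlation",
                "kind": kind,
                "r_ynm_om": r_om,
                "r_ynm_onm": r_onm,
                "r_om_onm": r_older,
                "steiger_z_om_vs_onm": z,
                "n_pairs": n,
            }
        )
    return records


def run_full(config: RunConfig) -> RunReport:
    """Execute the whole pipeline and write all outputs under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.simulate:
        log.info("simulating cohort (seed=%d)", config.seed)
        link = BehaviorLinkSpec(**config.link) if config.link else None
        atlas_sim = make_atlas(config.pairs_per_network, seed=config.seed) if config.pairs_per_network else None
        data = make_cohort(
            group_sizes=config.group_sizes,
            plans=default_plans(),
            link=link,
            seed=config.seed,
            atlas=atlas_sim,
            n_timepoints=config.n_timepoints,
        )
        atlas, cohort, timeseries, fd = data.atlas, data.cohort, data.timeseries, data.fd
    else:
        if not (config.atlas_path and config.cohort_path and config.timeseries_dir):
            raise ValueError("non-simulated runs need atlas_path, cohort_path and timeseries_dir")
        atlas = load_atlas(config.atlas_path)
        cohort = load_cohort(config.cohort_path)
        ts_dir = Path(config.timeseries_dir)
        timeseries, fd = {}, {}
        for sid in cohort.subjects():
            for ext in ("ts.tsv", "ts.bin"):
                p = ts_dir / f"{sid}.{ext}"
                if p.exists():
                    timeseries[sid] = load_timeseries(p, atlas)
                    break
            else:
                raise FileNotFoundError(f"no time series for subject {sid!r} under {ts_dir}")
            fd_path = ts_dir / f"{sid}.fd.tsv"
            if fd_path.exists():
                fd[sid] = load_fd(fd_path)

    limaps, nli_table, qc_table, excluded = compute_subject_measures(atlas, timeseries, fd, config)
    keep = set(limaps)
    cohort_used = CohortTable(cohort.table[cohort.table["subject_id"].isin(keep)])
    align_table, align_warnings = compute_alignment(limaps, atlas, cohort_used, config.template_mode)

    nli_long = nli_table.melt(
        id_vars=["subject_id", "network"],
        value_vars=[f"li_{k}" for k in LI_KINDS],
        var_name="kind",
        value_name="li",
    )
    nli_long["kind"] = nli_long["kind"].str.removeprefix("li_")

    records: list[dict] = []
    warnings: list[dict] = list(align_warnings)
    order = _present_groups(cohort_used)
    if len(order) >= 2:
        records += _anova_battery(nli_long, "li", cohort_used, jt_direction=None)
        jt_dir = config.jt_direction if len(order) >= 3 else None
        if jt_dir is None:
            warnings.append({"stage": "jt", "warning": "Jonckheere-Terpstra requires >= 3 groups; skipped"})
        align_long = align_table.rename(columns={"alignment": "value"})
        records += _anova_battery(align_long, "value", cohort_used, jt_direction=jt_dir)
        records += _behavior_correlations(nli_long, "li", cohort_used, config.covariates)
        records += _behavior_correlations(align_long, "value", cohort_used, config.covariates)
    map_records = _map_comparisons(limaps, cohort_used)
    table1 = run_table1(cohort_used) if len(order) >= 3 else []

    # outputs
    nli_table.to_csv(out / "network_li.tsv", sep="\t", index=False)
    align_table.to_csv(out / "alignment.tsv", sep="\t", index=False)
    if len(qc_table):
        qc_table.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    results = {
        "statistics": records,
        "map_comparisons": map_records,
        "table1": table1,
    }
    (out / "results_stats.json").write_text(json.dumps(results, indent=1, sort_keys=True, default=float))
    report = RunReport(
        config_hash=config.config_hash(),
        seed=config.seed,
        version=__version__,
        n_subjects_in=len(cohort.table),
        excluded=excluded,
        stage_counts={
            "subjects_used": len(limaps),
            "network_li_rows": len(nli_table),
            "alignment_rows": len(align_table),
            "stat_records": len(records),
        },
        warnings=warnings,
    )
    (out / "run_report.json").write_text(json.dumps(asdict(report), indent=1, sort_keys=True, default=float))
    return report
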