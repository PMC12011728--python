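"""Orchestration: simulate -> preprocess -> CSP -> NF -> ERD -> stats.

Per session block the online path mirrors the run-chaining of the emulated
protocol: the training run (T) fits CSP filters, the classifier triplet and
borders that calibrate NF1; NF1 fits calibrate NF2. No classifier ever
scores the run it was trained on, and the manifest records the chain. The
offline path fits one block-level CSP over all three runs pooled and
produces the per-participant, per-block ERD summaries that feed the group
statistics.

Everything is deterministic under the config seed: per-subject seeds are
derived from independent child streams, so the same config yields
byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from minf import erd as erd_mod
from minf import stats as stats_mod
from minf.csp import fit_csp, select_filters, apply_csp, project_selected
from minf.neurofeedback import (
    extract_features,
    train_classifier_triplet,
    classify_stream,
    feedback_trace,
)
from minf.preprocessing import (
    ChannelQCConfig,
    NF_BANDPASS,
    OFFLINE_HIGHPASS,
    OFFLINE_LOWPASS,
    baseline_correct,
    concat_epochs,
    detect_bad_channels,
    epoch_data,
    fir_filter,
    prepare_reference,
    artifact_mask,
)
from minf.simulate import (
    RUN_NAMES,
    SimulationConfig,
    central_channel_subset,
    generate_schedule,
    simulate_recording,
)

GROUPS = ("quiet_rest", "documentaries")

TABLE1_COLUMNS = ["block", "t", "df", "p", "p_holm", "d", "ci_low", "ci_high",
                  "N", "M_T", "SD_T", "M_NF", "SD_NF"]
TABLE2_COLUMNS = ["block", "t", "df", "p", "p_holm", "d", "ci_low", "ci_high",
                  "N", "M_QR", "SD_QR", "M_D", "SD_D"]


@dataclass
class PipelineConfig:
    """Resolved configuration of one full synthetic experiment."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    qc: ChannelQCConfig = field(default_factory=ChannelQCConfig)
    n_subjects_per_group: int = 17
    n_central_channels: int = 49
    csp_window: tuple[float, float] = (0.5, 4.5)
    csp_shrinkage: float = 0.05
    csp_selection_mode: str = "eigenvalue"
    nf_folds: int = 7
    epoch_window: tuple[float, float] = (-7.0, 9.0)
    baseline_interval: tuple[float, float] = (-6.0, -4.0)
    mi_summary_window: tuple[float, float] = (0.5, 4.5)
    erd_smooth: float = 0.25
    #: extra ERD depth during NF runs relative to the training run — the
    #: built-in neurofeedback benefit the paired tests should detect
    nf_depth_boost: float = 0.15
    #: per-block depth offset for the documentaries group (0 = identical
    #: groups, matching the emulated study's null result)
    group_effect: float = 0.0
    holm_variant: str = "standard"
    online: bool = True
    seed: int = 0

    def subject_seed(self, group: str, subject: int) -> int:
        ss = np.random.SeedSequence(
            entropy=int(self.seed), spawn_key=(GROUPS.index(group), subject)
        )
        return int(ss.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    """Stage bookkeeping: hashes, trial counts, and the calibration chain."""

    stages: list = field(default_factory=list)

    def add(self, stage: str, **info) -> None:
        self.stages.append(dict(stage=stage, **info))

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.stages, indent=1, default=str)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def audit_no_leakage(self) -> bool:
        """True iff every classifier scored a run other than its training run."""
        for s in self.stages:
            if s["stage"] == "score-nf" and s["trained_on"] == s["scored_on"]:
                return False
        return True


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]


def _simulate_run(cfg: PipelineConfig, run: str, block: int, seed: int,
                  depth_offset: float = 0.0):
    """One run's recording on its own timeline (memory-light)."""
    boost = cfg.nf_depth_boost if run in ("NF1", "NF2") else 0.0
    sim = cfg.sim.replace(
        n_blocks=1,
        n_runs_per_block=1,
        erd_depth_mu=float(np.clip(cfg.sim.erd_depth_mu + boost + depth_offset, 0, 1)),
        erd_depth_beta=float(np.clip(cfg.sim.erd_depth_beta + boost + depth_offset, 0, 1)),
        seed=seed,
    )
    schedule = generate_schedule(sim)
    schedule["run"] = run
    schedule["block"] = block
    rec = simulate_recording(sim, schedule)
    return rec


def _offline_epochs(cfg: PipelineConfig, rec, manifest: RunManifest):
    """Offline preprocessing of one run: filter, epoch, QC, reference."""
    filtered = fir_filter(fir_filter(rec, OFFLINE_HIGHPASS), OFFLINE_LOWPASS)
    bad = detect_bad_channels(filtered, cfg.qc)
    ep = epoch_data(filtered, filtered.events, cfg.epoch_window)
    ep = baseline_correct(ep, cfg.baseline_interval)
    ep = prepare_reference(ep, bad)
    central = central_channel_subset(ep.channel_positions, cfg.n_central_channels)
    ep = dataclasses.replace(
        ep,
        data=ep.data[:, central, :],
        channel_labels=[ep.channel_labels[i] for i in central],
        channel_positions=ep.channel_positions[central],
    )
    artifact_mask(ep, cfg.qc, method="amplitude")
    manifest.add(
        "preprocess", run=str(rec.events["run"].iloc[0]),
        block=int(rec.events["block"].iloc[0]),
        bad_channels=bad, kept=int(ep.kept.sum()),
        rejected=int(ep.rejected.sum()), dropped=ep.n_dropped,
        data_hash=_hash(ep.data),
    )
    return ep


def _online_block(cfg: PipelineConfig, recs: dict, block: int,
                  manifest: RunManifest, seed: int) -> dict:
    """Run-chained NF calibration: T calibrates NF1, NF1 calibrates NF2."""
    central = None
    eps = {}
    for run, rec in recs.items():
        filtered = fir_filter(rec, NF_BANDPASS)
        ep = epoch_data(filtered, filtered.events, cfg.epoch_window)
        if central is None:
            central = central_channel_subset(ep.channel_positions,
                                             cfg.n_central_channels)
        eps[run] = dataclasses.replace(
            ep,
            data=ep.data[:, central, :],
            channel_labels=[ep.channel_labels[i] for i in central],
            channel_positions=ep.channel_positions[central],
        )

    accuracies = {}
    triplet = None
    trained_on = None
    for prev, cur in (("T", "NF1"), ("NF1", "NF2")):
        model = select_filters(
            fit_csp(eps[prev], cfg.csp_window, cfg.csp_shrinkage),
            1, mode=cfg.csp_selection_mode,
        )
        proj_prev = project_selected(eps[prev], model)
        mi = extract_features(proj_prev, "MI")
        base = extract_features(proj_prev, "baseline")
        triplet = train_classifier_triplet(mi, base, k=cfg.nf_folds,
                                           seed=seed, run=prev)
        trained_on = prev
        manifest.add("train-nf", block=block, trained_on=prev,
                     lr_cv_accuracy=float(triplet.LR.cv_accuracy),
                     borders={k: float(v) for k, v in triplet.borders.items()})
        proj_cur = project_selected(eps[cur], model)
        mi_cur = extract_features(proj_cur, "MI")
        trace = feedback_trace(mi_cur, triplet)
        scores = classify_stream(mi_cur, triplet)
        # lateralization sanity: mean x should track the instructed hand
        x_signed = np.where(mi_cur.labels[:, None] == "right", 1, -1)
        accuracies[cur] = dict(
            lr_cv_accuracy=float(triplet.LR.cv_accuracy),
            base_l_cv_accuracy=float(triplet.BaseL.cv_accuracy),
            base_r_cv_accuracy=float(triplet.BaseR.cv_accuracy),
            mean_correct_x=float((trace[:, :, 0] * x_signed).mean()),
            mean_y=float(trace[:, :, 1].mean()),
        )
        manifest.add("score-nf", block=block, trained_on=trained_on,
                     scored_on=cur, n_trials=int(mi_cur.n_trials),
                     scores_hash=_hash(scores["LR"]))
    return accuracies


def run_subject(cfg: PipelineConfig, participant: str, group: str,
                subject: int, manifest: RunManifest) -> list:
    """All blocks of one synthetic participant -> ERD block summaries."""
    seed = cfg.subject_seed(group, subject)
    depth_offset = cfg.group_effect if group == "documentaries" else 0.0
    summaries = []
    for block in range(1, cfg.sim.n_blocks + 1):
        recs = {}
        for r_i, run in enumerate(RUN_NAMES[: cfg.sim.n_runs_per_block]):
            run_seed = (seed + 1000 * block + r_i) % (2**31)
            recs[run] = _simulate_run(cfg, run, block, run_seed, depth_offset)
            manifest.add("simulate", participant=participant, block=block,
                         run=run, seed=run_seed,
                         n_events=len(recs[run].events))
        if cfg.online and cfg.sim.n_runs_per_block >= 3:
            _online_block(cfg, recs, block, manifest, seed)

        # offline path: block-level CSP over the three runs pooled
        eps = {run: _offline_epochs(cfg, rec, manifest)
               for run, rec in recs.items()}
        pooled = concat_epochs(list(eps.values()))
        model = select_filters(
            fit_csp(pooled, cfg.csp_window, cfg.csp_shrinkage),
            1, mode=cfg.csp_selection_mode,
        )
        manifest.add("fit-csp", participant=participant, block=block,
                     level="block", eigenvalues_extreme=(
                         float(model.eigenvalues[0]), float(model.eigenvalues[-1])))

        tcs = {}
        for run, ep in eps.items():
            proj = apply_csp(ep, model, "contra")
            per_hand = []
            for hand in ("left", "right"):
                sub = proj.select(proj.labels == hand)
                per_hand.append(erd_mod.compute_erd(
                    sub, cfg.baseline_interval, cfg.erd_smooth,
                    laterality="contra", run=run, block=block))
            tcs[run] = erd_mod.average_contralateral(*per_hand)
        nf_pooled = concat_epochs([
            apply_csp(eps["NF1"], model, "contra"),
            apply_csp(eps["NF2"], model, "contra"),
        ]) if "NF2" in eps else apply_csp(eps["NF1"], model, "contra")
        tcs["NF"] = erd_mod.compute_erd(
            nf_pooled, cfg.baseline_interval, cfg.erd_smooth,
            laterality="contra", run="NF", block=block, hand_pooled=True)
        bp = erd_mod.baseline_power(nf_pooled, cfg.baseline_interval)
        summaries.append(erd_mod.summarize_block(
            tcs, participant=participant, group=group, block=block,
            mi_window=cfg.mi_summary_window, baseline_power_value=bp))
    return summaries


def stats_from_summaries(summaries: pd.DataFrame,
                         holm_variant: str = "standard") -> dict:
    """Table-1/Table-2 analogues and the mixed rmANOVA from a summary table.

    Deterministic function of the summary table alone, so exporting the
    table and re-running this stage reproduces identical statistics.
    """
    out: dict = {}
    qr = summaries[summaries["group"] == "quiet_rest"]
    rows = []
    for block, sub in qr.groupby("block"):
        sub = sub.sort_values("participant")
        res = stats_mod.paired_ttest(sub["T_MI_ERD"], sub["NF_MI_ERD"],
                                     alternative="greater")
        rows.append(dict(block=block, t=res.t, df=res.df, p=res.p,
                         p_holm=np.nan, d=res.d, ci_low=res.ci[0],
                         ci_high=res.ci[1], N=res.n, M_T=res.mean_a,
                         SD_T=res.sd_a, M_NF=res.mean_b, SD_NF=res.sd_b))
    t1 = pd.DataFrame(rows, columns=TABLE1_COLUMNS)
    if len(t1):
        t1["p_holm"] = stats_mod.holm_adjust(t1["p"].to_numpy(), holm_variant)
    out["table1"] = t1

    if set(summaries["group"]) >= {"quiet_rest", "documentaries"}:
        doc = summaries[summaries["group"] == "documentaries"]
        rows = []
        for block in sorted(summaries["block"].unique()):
            a = doc[doc["block"] == block]["NF_MI_ERD"].to_numpy()
            b = qr[qr["block"] == block]["NF_MI_ERD"].to_numpy()
            res = stats_mod.independent_ttest(a=a, b=b)  # documentaries - QR
            if min(len(a), len(b)) >= 3:
                checks = stats_mod.assumption_checks(a, b)
            else:
                checks = {"shapiro_p": (np.nan, np.nan), "levene_p": np.nan}
            rows.append(dict(block=block, t=res.t, df=res.df, p=res.p,
                             p_holm=np.nan, d=res.d, ci_low=res.ci[0],
                             ci_high=res.ci[1], N=res.n, M_QR=res.mean_b,
                             SD_QR=res.sd_b, M_D=res.mean_a, SD_D=res.sd_a,
                             shapiro_p_doc=checks["shapiro_p"][0],
                             shapiro_p_qr=checks["shapiro_p"][1],
                             levene_p=checks["levene_p"]))
        t2 = pd.DataFrame(rows, columns=TABLE2_COLUMNS
                          + ["shapiro_p_doc", "shapiro_p_qr", "levene_p"])
        if len(t2):
            t2["p_holm"] = stats_mod.holm_adjust(t2["p"].to_numpy(), holm_variant)
        out["table2"] = t2

        if summaries["block"].nunique() >= 2:
            anova_tbl = summaries.rename(columns={"NF_MI_ERD": "value"})[
                ["participant", "group", "block", "value"]]
            out["anova"] = pd.DataFrame([dataclasses.asdict(r) for r in
                                         stats_mod.rm_anova_mixed(anova_tbl)])
        else:
            out["anova"] = pd.DataFrame()

        rows = []
        for block in sorted(summaries["block"].unique()):
            a = doc[doc["block"] == block]["baseline_power"].to_numpy()
            b = qr[qr["block"] == block]["baseline_power"].to_numpy()
            res = stats_mod.independent_ttest(a=a, b=b)
            rows.append(dict(block=block, t=res.t, df=res.df, p=res.p, d=res.d))
        out["baseline_power"] = pd.DataFrame(rows)
    else:
        if qr["block"].nunique() >= 2:
            anova_tbl = qr.rename(columns={"NF_MI_ERD": "value"})[
                ["participant", "block", "value"]]
            out["anova"] = pd.DataFrame([dataclasses.asdict(r) for r in
                                         stats_mod.rm_anova_mixed(anova_tbl)])
        else:
            out["anova"] = pd.DataFrame()
    return out


def run_full_pipeline(cfg: PipelineConfig, two_groups: bool = True
                      ) -> tuple[RunManifest, pd.DataFrame, dict]:
    """Full synthetic experiment -> (manifest, ERD summaries, stats tables)."""
    import minf

    manifest = RunManifest()
    manifest.add("config", resolved=cfg.to_dict(), software=f"minf {minf.__version__}")
    summaries = []
    groups = GROUPS if two_groups else GROUPS[:1]
    for group in groups:
        for s in range(cfg.n_subjects_per_group):
            pid = f"{'qr' if group == 'quiet_rest' else 'doc'}{s + 1:02d}"
            summaries.extend(run_subject(cfg, pid, group, s, manifest))
    frame = erd_mod.summaries_to_frame(summaries)
    tables = stats_from_summaries(frame, cfg.holm_variant)
    if not manifest.audit_no_leakage():
        raise RuntimeError("leakage audit failed: classifier scored its own run")
    manifest.add("stats", tables=sorted(tables))
    return manifest, frame, tables


def export_tables(summaries: pd.DataFrame, tables: dict, outdir: str) -> list[str]:
    """Write the ERD summary and statistics tables as CSV; returns paths."""
    if summaries is None or len(summaries) == 0:
        raise ValueError("no block summaries to export (erd stage missing?)")
    os.makedirs(outdir, exist_ok=True)
    paths = []
    p = os.path.join(outdir, "erd_block_summaries.csv")
    summaries.to_csv(p, index=False)
    paths.append(p)
    for name, tbl in tables.items():
        p = os.path.join(outdir, f"{name}.csv")
        tbl.to_csv(p, index=False)
        paths.append(p)
    return paths
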