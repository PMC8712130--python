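"""End-to-end orchestration: simulate -> preprocess -> spectral -> stats.

One :func:`run_pipeline` call simulates a cohort, cleans and epochs every
session, computes IAF-relative cluster band powers and the engagement
index, scores behavior, and runs the 2x3 load-by-modality statistics,
producing a reproducible report.  All randomness flows from the single
master seed in the config, split per subject and stage, so identical
(config, seed) yields identical reports.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import preprocess, protocol, spectral, stats, synth
from .montage import CLUSTERS
from .preprocess import ArtifactCriteria
from .protocol import LEVELS, MODALITIES

logger = logging.getLogger(__name__)

#: The cluster/band combinations entered into the neurophysiological ANOVA.
DEFAULT_ANOVA_COMBOS = (
    ("frontal", "theta"),
    ("midline", "theta"),
    ("left_hemisphere", "theta"),
    ("parietal", "gamma"),
)

DEFAULT_CLUSTERS = ("frontal", "parietal", "occipital", "midline",
                    "left_hemisphere", "right_hemisphere")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int = 0
    n_subjects: int = 11
    cohort: synth.CohortConfig = field(default_factory=synth.CohortConfig)
    criteria: ArtifactCriteria = field(default_factory=ArtifactCriteria)
    normalization: str = "ratio"            # "ratio" | "db"
    clusters: tuple = DEFAULT_CLUSTERS
    anova_combos: tuple = DEFAULT_ANOVA_COMBOS
    anova_method: str = "auto"              # "auto" | "parametric" | "rank"
    anova_design: str = "within"
    alpha: float = 0.05
    out_dir: Optional[str] = None

    def to_yaml(self) -> str:
        d = asdict(self)
        d["clusters"] = list(self.clusters)
        d["anova_combos"] = [list(c) for c in self.anova_combos]
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        if "cohort" in d:
            d["cohort"] = synth.CohortConfig(**d["cohort"])
        if "criteria" in d:
            d["criteria"] = ArtifactCriteria(**d["criteria"])
        if "clusters" in d:
            d["clusters"] = tuple(d["clusters"])
        if "anova_combos" in d:
            d["anova_combos"] = tuple(tuple(c) for c in d["anova_combos"])
        return cls(**d)


@dataclass
class RunReport:
    behavior: pd.DataFrame
    anova_behavior: pd.DataFrame
    cluster_power: pd.DataFrame
    engagement: pd.DataFrame
    anova_eeg: pd.DataFrame
    posthoc: pd.DataFrame
    correlation: pd.DataFrame
    qc: pd.DataFrame
    provenance: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = dict(sep="\t", index=False, float_format="%.10g")
        self.behavior.to_csv(out / "behavior.tsv", **fmt)
        self.anova_behavior.to_csv(out / "anova_behavior.tsv", **fmt)
        self.cluster_power.to_csv(out / "cluster_power.tsv", **fmt)
        self.engagement.to_csv(out / "engagement.tsv", **fmt)
        self.anova_eeg.to_csv(out / "anova_eeg.tsv", **fmt)
        self.posthoc.to_csv(out / "posthoc.tsv", **fmt)
        self.correlation.to_csv(out / "correlation.tsv", **fmt)
        self.qc.to_csv(out / "qc.tsv", **fmt)
        with open(out / "provenance.yaml", "w") as fh:
            yaml.safe_dump(self.provenance, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# per-session processing

def process_session(recording, plan, criteria: ArtifactCriteria | None = None,
                    normalization: str = "ratio",
                    clusters=DEFAULT_CLUSTERS) -> dict:
    """Clean one session and reduce it to per-condition cluster band powers.

    Returns a dict with the IAF, the per-level cluster power rows, the
    per-level engagement index (computed per epoch from the 19-channel raw
    band powers, then averaged), and QC counts.
    """
    criteria = criteria or ArtifactCriteria()
    filtered = preprocess.filter_recording(recording)
    cleaned = preprocess.remove_blinks(filtered)

    iaf = spectral.estimate_iaf(cleaned)
    scheme = spectral.band_scheme(iaf)

    events = synth.make_events(plan, recording.closed_eyes_s * 1000.0)
    epochs = preprocess.epoch_recording(cleaned, events)
    preprocess.detect_artifacts(epochs, criteria)
    qc = preprocess.qc_counts(epochs)
    clean = epochs.drop_artifacts()

    meta = clean.metadata
    power, band_names = spectral.compute_band_power(clean, scheme)

    is_baseline = (meta["kind"] == "baseline").to_numpy()
    if not is_baseline.any():
        raise RuntimeError(
            f"session {plan.subject_id}/{plan.modality}: every baseline epoch "
            f"was rejected; cannot normalize")
    baseline_mean = power[is_baseline].mean(axis=0)       # (ch, band)

    b_ix = {b: k for k, b in enumerate(band_names)}
    ei_cluster = CLUSTERS["ei_set"]
    rows, ei_rows = [], []
    for level in LEVELS:
        in_level = ((meta["kind"] == "task") & (meta["level"] == level)).to_numpy()
        if not in_level.any():
            raise RuntimeError(
                f"session {plan.subject_id}/{plan.modality}: no clean epochs "
                f"at level {level}")
        task_power = power[in_level]                       # (ep, ch, band)
        norm = spectral.baseline_normalize(task_power, baseline_mean[None],
                                           mode=normalization)
        cell_norm = norm.mean(axis=0)                      # (ch, band)
        for cname in clusters:
            cl = CLUSTERS[cname]
            cl_power = spectral.cluster_average(cell_norm, clean.ch_names, cl,
                                                channel_axis=0)
            for band in band_names:
                rows.append({"subject": plan.subject_id,
                             "modality": plan.modality, "level": level,
                             "cluster": cname, "band": band,
                             "normalized_power": float(cl_power[b_ix[band]])})
        # engagement index per epoch from raw 19-channel band powers
        cl_raw = spectral.cluster_average(task_power, clean.ch_names,
                                          ei_cluster, channel_axis=1)
        ei = spectral.engagement_index(cl_raw[:, b_ix["beta"]],
                                       cl_raw[:, b_ix["alpha"]],
                                       cl_raw[:, b_ix["theta"]])
        ei_rows.append({"subject": plan.subject_id, "modality": plan.modality,
                        "level": level, "ei": float(ei.mean())})
    return {"iaf_hz": iaf, "cluster_rows": rows, "ei_rows": ei_rows,
            "qc": qc.assign(subject=plan.subject_id, modality=plan.modality)}


def score_behavior(responses, plan) -> list[dict]:
    rows = []
    for level in LEVELS:
        sc = protocol.score_condition(responses, plan, level)
        rows.append({"subject": sc.subject_id, "modality": sc.modality,
                     "level": sc.level, "acc": sc.acc,
                     "mean_rt_correct_ms": sc.mean_rt_correct_ms,
                     "pe": sc.pe, "ies_ms": sc.ies_ms})
    return rows


# ---------------------------------------------------------------------------
# cohort-level statistics

def _anova_rows(anova: stats.AnovaResult, **context) -> list[dict]:
    rows = []
    for eff in anova.effects.values():
        rows.append({**context, "effect": eff.effect, "F": eff.F,
                     "df_effect": eff.df_effect, "df_error": eff.df_error,
                     "p": eff.p, "partial_eta_sq": eff.partial_eta_sq,
                     "method": anova.method})
    return rows


def _posthoc_rows(table, anova, alpha, **context) -> list[dict]:
    rows = []
    for eff in anova.effects.values():
        if eff.p >= alpha:
            continue
        ph = stats.duncan_posthoc(table, eff.effect, anova, alpha=alpha)
        for _, r in ph.comparisons.iterrows():
            rows.append({**context, "effect": eff.effect, **r.to_dict()})
    return rows


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis on a simulated cohort."""
    logger.info("simulating cohort: %d subjects, seed %d",
                config.n_subjects, config.seed)
    cohort_cfg = config.cohort
    cohort_cfg.n_subjects = config.n_subjects
    profiles, sessions = synth.make_cohort(
        n_subjects=config.n_subjects, effect_config=cohort_cfg,
        seed=config.seed, out_dir=None)

    behavior_rows, cluster_rows, ei_rows, qc_rows = [], [], [], []
    iaf_by_subject = {}
    for (sid, modality), sess in sorted(sessions.items()):
        try:
            res = process_session(sess["recording"], sess["plan"],
                                  criteria=config.criteria,
                                  normalization=config.normalization,
                                  clusters=config.clusters)
        except Exception as exc:
            raise RuntimeError(
                f"preprocessing/spectral stage failed for subject {sid}, "
                f"modality {modality}: {exc}") from exc
        cluster_rows.extend(res["cluster_rows"])
        ei_rows.extend(res["ei_rows"])
        qc_rows.append(res["qc"])
        iaf_by_subject.setdefault(sid, {})[modality] = res["iaf_hz"]
        behavior_rows.extend(score_behavior(sess["responses"], sess["plan"]))

    behavior = pd.DataFrame(behavior_rows).sort_values(
        ["subject", "modality", "level"]).reset_index(drop=True)
    cluster_power = pd.DataFrame(cluster_rows)
    engagement = pd.DataFrame(ei_rows).sort_values(
        ["subject", "modality", "level"]).reset_index(drop=True)
    qc = pd.concat(qc_rows, ignore_index=True)[
        ["subject", "modality", "n_epochs", "n_artifact", "n_threshold",
         "n_trend", "n_jump"]]

    # behavioral ANOVAs
    anova_b_rows, posthoc_rows = [], []
    for measure, col in (("rt", "mean_rt_correct_ms"), ("acc", "acc"),
                         ("ies", "ies_ms")):
        tbl = behavior.rename(columns={col: "value"})[
            ["subject", "modality", "level", "value"]].dropna()
        an = stats.factorial_anova(tbl, method=config.anova_method,
                                   design=config.anova_design,
                                   alpha=config.alpha)
        anova_b_rows.extend(_anova_rows(an, measure=measure))
        posthoc_rows.extend(_posthoc_rows(tbl, an, config.alpha,
                                          measure=measure))
    anova_behavior = pd.DataFrame(anova_b_rows)

    # neurophysiological ANOVAs: selected cluster/band combos plus EI
    anova_e_rows = []
    for cname, band in config.anova_combos:
        sub = cluster_power[(cluster_power["cluster"] == cname)
                            & (cluster_power["band"] == band)]
        tbl = sub.rename(columns={"normalized_power": "value"})[
            ["subject", "modality", "level", "value"]]
        an = stats.factorial_anova(tbl, method=config.anova_method,
                                   design=config.anova_design,
                                   alpha=config.alpha)
        anova_e_rows.extend(_anova_rows(an, cluster=cname, band=band))
        posthoc_rows.extend(_posthoc_rows(tbl, an, config.alpha,
                                          cluster=cname, band=band))
    ei_tbl = engagement.rename(columns={"ei": "value"})[
        ["subject", "modality", "level", "value"]]
    an = stats.factorial_anova(ei_tbl, method=config.anova_method,
                               design=config.anova_design, alpha=config.alpha)
    anova_e_rows.extend(_anova_rows(an, cluster="ei_set", band="ei"))
    posthoc_rows.extend(_posthoc_rows(ei_tbl, an, config.alpha,
                                      cluster="ei_set", band="ei"))
    anova_eeg = pd.DataFrame(anova_e_rows)
    posthoc = pd.DataFrame(posthoc_rows)

    # EI-RT correlation across subject x condition cells
    merged = engagement.merge(behavior, on=["subject", "modality", "level"])
    merged = merged.dropna(subset=["ei", "mean_rt_correct_ms"])
    r, p = stats.correlate(merged["ei"], merged["mean_rt_correct_ms"])
    correlation = pd.DataFrame([{"x": "ei", "y": "mean_rt_correct_ms",
                                 "n": len(merged), "r": r, "p": p}])

    config_yaml = config.to_yaml()
    provenance = {
        "seed": int(config.seed),
        "n_subjects": int(config.n_subjects),
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "iaf_hz": {s: {m: round(float(v), 4) for m, v in d.items()}
                   for s, d in iaf_by_subject.items()},
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }

    report = RunReport(behavior=behavior, anova_behavior=anova_behavior,
                       cluster_power=cluster_power, engagement=engagement,
                       anova_eeg=anova_eeg, posthoc=posthoc,
                       correlation=correlation, qc=qc, provenance=provenance)
    if config.out_dir:
        report.write(config.out_dir)
    return report


# ---------------------------------------------------------------------------
# scaled-down replicate studies
#
# These run the generative model at epoch level (no continuous recording,
# no filtering/blink stage) so that hundreds of replicate cohorts fit in a
# routine test run; band power, normalization, clustering and statistics go
# through the same spectral/stats code paths as the full pipeline.

_THETA_STUDY_CHANNELS = ("F3", "F4", "F7", "F8", "Fz", "Cz", "Pz")


def theta_load_replicate(seed, config: Optional[synth.CohortConfig] = None,
                         n_subjects: int = 11, n_epochs_per_cell: int = 8
                         ) -> dict:
    """One simulated cohort reduced to frontal/midline theta load p-values.

    Per subject and condition cell, ``n_epochs_per_cell`` stimulus epochs
    are simulated over the frontal and midline channels, theta band power
    (IAF-relative) is averaged and baseline-normalized, and the
    load-by-modality ANOVA is run per cluster.  Returns
    ``{cluster: p_load}``.
    """
    config = config or synth.CohortConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rows = []
    for i, sseq in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(sseq)
        prof = synth.draw_profile(config, f"s{i + 1:02d}", rng)
        scheme = spectral.band_scheme(prof.iaf_hz)
        base = synth.simulate_condition_epochs(
            prof, "audio", "baseline", n_epochs_per_cell,
            rng.integers(2 ** 31), channels=_THETA_STUDY_CHANNELS)
        base_p, bands = spectral.compute_band_power(base, scheme, fs=synth.FS,
                                                    bands=("theta",))
        base_theta = base_p.mean(axis=0)[:, 0]            # per channel
        for modality in MODALITIES:
            for level in LEVELS:
                ep = synth.simulate_condition_epochs(
                    prof, modality, level, n_epochs_per_cell,
                    rng.integers(2 ** 31), channels=_THETA_STUDY_CHANNELS)
                p_, _ = spectral.compute_band_power(ep, scheme, fs=synth.FS,
                                                    bands=("theta",))
                norm = spectral.baseline_normalize(p_.mean(axis=0)[:, 0],
                                                   base_theta)
                for cname in ("frontal", "midline"):
                    cl = CLUSTERS[cname]
                    val = spectral.cluster_average(
                        norm[:, None], _THETA_STUDY_CHANNELS, cl,
                        channel_axis=0)[0]
                    rows.append({"subject": prof.subject_id,
                                 "modality": modality, "level": level,
                                 "cluster": cname, "value": float(val)})
    df = pd.DataFrame(rows)
    out = {}
    for cname in ("frontal", "midline"):
        tbl = df[df["cluster"] == cname][["subject", "modality", "level",
                                          "value"]]
        an = stats.factorial_anova(tbl)
        out[cname] = an["level"].p
    return out


def theta_power_study(n_replicates: int, seed,
                      theta_load_gain_mean: Optional[float] = None,
                      n_subjects: int = 11, n_epochs_per_cell: int = 8,
                      alpha: float = 0.05) -> dict:
    """Fraction of replicate cohorts whose theta load effect is significant.

    ``theta_load_gain_mean=1.0`` (with zero spread) gives the null
    calibration; ``None`` keeps the default injected gain.
    """
    config = synth.CohortConfig()
    if theta_load_gain_mean is not None:
        config.theta_load_gain_mean = theta_load_gain_mean
        if theta_load_gain_mean == 1.0:
            config.theta_load_gain_sd = 0.0
    ss = np.random.SeedSequence(seed)
    hits = {"frontal": 0, "midline": 0}
    for rep_seq in ss.spawn(n_replicates):
        ps = theta_load_replicate(rep_seq, config, n_subjects,
                                  n_epochs_per_cell)
        for cname, p in ps.items():
            hits[cname] += p < alpha
    return {cname: hits[cname] / n_replicates for cname in hits}


def ei_rt_replicate(seed, config: Optional[synth.CohortConfig] = None,
                    n_subjects: int = 11, n_epochs_per_cell: int = 6) -> float:
    """Cell-level Pearson r between the engagement index and mean correct RT
    for one simulated cohort (subject x modality x level cells)."""
    config = config or synth.CohortConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    ei_vals, rt_vals = [], []
    ei_cluster = CLUSTERS["ei_set"]
    for i, sseq in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(sseq)
        prof = synth.draw_profile(config, f"s{i + 1:02d}", rng)
        scheme = spectral.band_scheme(prof.iaf_hz)
        for modality in MODALITIES:
            plan = protocol.generate_session(prof.subject_id, modality,
                                             int(rng.integers(2 ** 31)))
            responses = synth.simulate_behavior(prof, plan,
                                                int(rng.integers(2 ** 31)))
            for level in LEVELS:
                ep = synth.simulate_condition_epochs(
                    prof, modality, level, n_epochs_per_cell,
                    rng.integers(2 ** 31), channels=ei_cluster.channels)
                p_, bands = spectral.compute_band_power(
                    ep, scheme, fs=synth.FS, bands=("theta", "alpha", "beta"))
                cl = spectral.cluster_average(p_, ei_cluster.channels,
                                              ei_cluster, channel_axis=1)
                b_ix = {b: k for k, b in enumerate(bands)}
                ei = spectral.engagement_index(cl[:, b_ix["beta"]],
                                               cl[:, b_ix["alpha"]],
                                               cl[:, b_ix["theta"]])
                sc = protocol.score_condition(responses, plan, level)
                if sc.mean_rt_correct_ms is None:
                    continue
                ei_vals.append(float(ei.mean()))
                rt_vals.append(sc.mean_rt_correct_ms)
    r, _ = stats.correlate(ei_vals, rt_vals)
    return r


def ei_rt_coupling_study(n_replicates: int, seed, n_subjects: int = 11,
                         n_epochs_per_cell: int = 6) -> dict:
    """Sign-stability of the EI-RT correlation across replicate cohorts."""
    ss = np.random.SeedSequence(seed)
    rs = [ei_rt_replicate(s, n_subjects=n_subjects,
                          n_epochs_per_cell=n_epochs_per_cell)
          for s in ss.spawn(n_replicates)]
    rs = np.asarray(rs)
    return {"mean_r": float(rs.mean()),
            "frac_negative": float((rs < 0).mean())}
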