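"""End-to-end orchestration: simulate -> stimuli -> score -> analyze -> power.

A single YAML config describes the experimental design (six conditions =
{silent gap, noise burst} x {high-context, low-context, everyday}, sixty
sentences each by default), the gating and level parameters, the scoring
rules, the analysis options and one master seed. ``run_pipeline`` executes
the stages in dependency order, writes every output under the configured
directory, and records a manifest of files with SHA-256 checksums so a
rerun with the same config and seed can be verified bit-for-bit. Stages
whose outputs already exist are skipped unless ``force`` is set, so deleting
one stage's outputs and rerunning regenerates only that stage and its
dependents.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .audio import read_wav, write_wav
from .autoscore import (KeywordList, ScoringRules, aggregate_condition,
                        read_keywords_csv, read_transcripts_csv, score_response)
from .cognitive import read_norms_csv, score_trial_log
from .gating import GatingSpec
from .noise import build_noise_model
from .power import PowerSpec, achieved_power, required_sample_size
from .regression import RestorationModel, purposeful_selection
from .simulate import (ABILITIES, CONDITIONS, SCREEN_COLUMNS, CohortSpec,
                       SentenceSpec, derive_seed, simulate_cohort,
                       simulate_transcripts, simulate_trial_logs,
                       synth_sentence, synthetic_dst_norms)
from .stats import (bonferroni_alpha, correlation_screen, describe,
                    fence_adjust, levene, pairwise_welch_bh, welch_anova)
from .stimuli import assemble_pair, measure_snr_db

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "DEFAULT_CONFIG"]

PREDICTORS = ["rst_percent", "stroop_interference", "stroop_speed_ms", "lextale_percent"]
SATURATED = PREDICTORS + [
    "dst_percentile", "flanker_interference_ms", "lextale_word_rt_ms",
    "age", "education", "ssq_speech", "ssq_spatial", "ssq_qualities",
]

DEFAULT_CONFIG = {
    "outdir": "runs/default",
    "design": {"conditions": list(CONDITIONS), "sentences_per_condition": 60},
    "gating": {"rate_hz": 2.0, "duty": 0.5, "start_phase": "speech_first", "ramp_ms": 10.0},
    "levels": {"snr_db": -10.0, "rms_target": 0.05, "rms_scope": "active_segments"},
    "noise": {"fft_policy": "concat"},
    "audio": {"sample_rate": 16000.0, "duration_s": 2.0},
    "cohort": {"n": 63, "residual_sd": 7.5},
    "transcripts": {"p_typo": 0.1},
    "scoring": {"double_letter": True, "transposition": True, "apostrophe": True},
    "analysis": {
        "fence_k": 3.0,
        "levene_center": "mean",
        "selection_p_stay": 0.25,
        "selection_delta_beta": 0.20,
        "literal_direction": False,
    },
    "power": {"f2": 0.3, "alpha": 0.05, "power": 0.9, "n_predictors": 4,
              "lambda_convention": "total_n"},
    "seed": 0,
}

_REQUIRED = [
    ("outdir",), ("design", "conditions"), ("design", "sentences_per_condition"),
    ("gating", "rate_hz"), ("gating", "duty"), ("gating", "ramp_ms"),
    ("levels", "snr_db"), ("levels", "rms_target"),
    ("audio", "sample_rate"), ("audio", "duration_s"),
    ("cohort", "n"), ("seed",),
]


class ConfigError(ValueError):
    """A required configuration key is missing or invalid."""


@dataclass
class RunConfig:
    """Validated run configuration (see DEFAULT_CONFIG for the schema)."""

    raw: dict

    def __post_init__(self) -> None:
        for path in _REQUIRED:
            node = self.raw
            for key in path:
                if not isinstance(node, dict) or key not in node:
                    raise ConfigError(f"missing config key: {'.'.join(path)}")
                node = node[key]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def default(cls, **overrides) -> "RunConfig":
        cfg = json.loads(json.dumps(DEFAULT_CONFIG))
        _deep_update(cfg, overrides)
        return cls(cfg)

    def __getitem__(self, key):
        return self.raw[key]

    def get(self, *path, default=None):
        node = self.raw
        for key in path:
            if not isinstance(node, dict) or key not in node:
                return default
            node = node[key]
        return node

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def outdir(self) -> Path:
        return Path(self.raw["outdir"])

    def gating_spec(self) -> GatingSpec:
        g = self.raw["gating"]
        return GatingSpec(g["rate_hz"], g["duty"],
                          g.get("start_phase", "speech_first"), g["ramp_ms"])

    def scoring_rules(self) -> ScoringRules:
        s = self.raw.get("scoring", {})
        return ScoringRules(
            double_letter=s.get("double_letter", True),
            transposition=s.get("transposition", True),
            apostrophe=s.get("apostrophe", True),
            custom_spellings=s.get("custom_spellings", {}) or {},
        )

    def sentence_ids(self) -> dict:
        """sentence_id -> condition for the whole design."""
        per = int(self.raw["design"]["sentences_per_condition"])
        out = {}
        for cond in self.raw["design"]["conditions"]:
            for i in range(per):
                out[f"{cond}_{i:03d}"] = cond
        return out


def _deep_update(base: dict, upd: dict) -> None:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_done(files) -> bool:
    return bool(files) and all(Path(f).exists() for f in files)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> list:
    """Cohort table, sentence audio + keywords, transcripts, trial logs."""
    out = cfg.outdir / "sim"
    out.mkdir(parents=True, exist_ok=True)
    audio_dir = out / "audio"
    audio_dir.mkdir(exist_ok=True)
    seed = cfg.seed

    cohort = simulate_cohort(CohortSpec(
        n=int(cfg.get("cohort", "n")),
        residual_sd=float(cfg.get("cohort", "residual_sd", default=7.5)),
        seed=derive_seed(seed, "cohort"),
    ))
    cohort.to_csv(out / "cohort.csv")
    truth_cols = [c for c in cohort.columns if c.startswith("z_")]
    cohort[truth_cols].to_csv(out / "ground_truth.csv")

    design = cfg.sentence_ids()
    fs = float(cfg.get("audio", "sample_rate"))
    dur = float(cfg.get("audio", "duration_s"))
    kw_rows = []
    for sid, cond in design.items():
        audio, kl = synth_sentence(SentenceSpec(
            duration_s=dur, sample_rate=fs, seed=derive_seed(seed, "sentence", sid)))
        write_wav(audio, audio_dir / f"{sid}.wav")
        kw_rows.append([sid, cond, *kl.keywords])
    with open(out / "keywords.csv", "w") as fh:
        fh.write("sentence_id,condition\n")  # ragged keyword columns follow
        for row in kw_rows:
            fh.write(",".join(map(str, row)) + "\n")

    # transcripts: per participant, report probability = condition score/100
    p_typo = float(cfg.get("transcripts", "p_typo", default=0.1))
    kls = {r[0]: KeywordList(r[0], tuple(r[2:])) for r in kw_rows}
    frames = []
    for pid, row in cohort.iterrows():
        for cond in cfg.raw["design"]["conditions"]:
            sids = [s for s, c in design.items() if c == cond]
            frames.append(simulate_transcripts(
                [kls[s] for s in sids], p_report=float(row[cond]) / 100.0,
                p_typo=p_typo, seed=derive_seed(seed, "transcripts"),
                participant_id=pid))
    pd.concat(frames, ignore_index=True).to_csv(out / "transcripts.csv", index=False)

    logs = simulate_trial_logs(cohort, derive_seed(seed, "logs"))
    logs.to_csv(out / "trial_logs.csv", index=False)
    norms = synthetic_dst_norms()
    pd.DataFrame({"total_correct": list(norms), "percentile": list(norms.values())}
                 ).to_csv(out / "dst_norms.csv", index=False)
    return [out / "cohort.csv", out / "ground_truth.csv", out / "keywords.csv",
            out / "transcripts.csv", out / "trial_logs.csv", out / "dst_norms.csv",
            *sorted(audio_dir.glob("*.wav"))]


def stage_stimuli(cfg: RunConfig) -> list:
    """Silent-gap / noise-burst WAV pairs + segment-map sidecars."""
    sim = cfg.outdir / "sim"
    out = cfg.outdir / "stimuli"
    out.mkdir(parents=True, exist_ok=True)
    spec = cfg.gating_spec()
    wavs = sorted((sim / "audio").glob("*.wav"))
    corpus = [read_wav(p) for p in wavs]
    model = build_noise_model(corpus, cfg.get("noise", "fft_policy", default="concat"))
    snr = float(cfg.get("levels", "snr_db"))
    target = float(cfg.get("levels", "rms_target"))
    scope = cfg.get("levels", "rms_scope", default="active_segments")
    files = []
    snr_rows = []
    for path, sentence in zip(wavs, corpus):
        sid = path.stem
        pair = assemble_pair(sentence, spec, model, snr_db=snr,
                             seed=derive_seed(cfg.seed, "noise", sid),
                             rms_target=target, rms_scope=scope)
        for tag, sig in (("silent", pair.silent_gap), ("noise", pair.noise_burst)):
            f = out / f"{sid}_{tag}.wav"
            write_wav(sig, f)
            files.append(f)
        mf = out / f"{sid}_segments.csv"
        pair.segment_map.to_csv(mf)
        files.append(mf)
        snr_rows.append({"sentence_id": sid, "measured_snr_db": measure_snr_db(pair)})
    pd.DataFrame(snr_rows).to_csv(out / "snr_check.csv", index=False)
    files.append(out / "snr_check.csv")
    return files


def stage_score(cfg: RunConfig) -> list:
    """Autoscore transcripts into per-condition percent correct."""
    sim = cfg.outdir / "sim"
    out = cfg.outdir / "scores"
    out.mkdir(parents=True, exist_ok=True)
    kls, design = read_keywords_csv(sim / "keywords.csv")
    by_id = {k.sentence_id: k for k in kls}
    rules = cfg.scoring_rules()
    transcripts = read_transcripts_csv(sim / "transcripts.csv")
    rows = []
    for pid, grp in transcripts.groupby("participant_id"):
        results = [score_response(by_id[r.sentence_id], r.transcript, rules)
                   for r in grp.itertuples()]
        percents = aggregate_condition(results, design,
                                       conditions=cfg.raw["design"]["conditions"])
        for cond, pct in percents.items():
            rows.append({"participant_id": pid, "condition": cond, "percent_correct": pct})
    pd.DataFrame(rows).to_csv(out / "condition_scores.csv", index=False)
    return [out / "condition_scores.csv"]


def stage_cognitive(cfg: RunConfig) -> list:
    """Score the cognitive/linguistic battery from the trial logs."""
    sim = cfg.outdir / "sim"
    out = cfg.outdir / "scores"
    out.mkdir(parents=True, exist_ok=True)
    logs = pd.read_csv(sim / "trial_logs.csv")
    norms = read_norms_csv(sim / "dst_norms.csv")
    measures = score_trial_log(logs, norms)
    measures.to_csv(out / "cognitive_measures.csv")
    return [out / "cognitive_measures.csv"]


def build_measure_table(cfg: RunConfig) -> pd.DataFrame:
    """Merge scored conditions + cognitive measures + demographics."""
    scores = pd.read_csv(cfg.outdir / "scores" / "condition_scores.csv")
    wide = scores.pivot(index="participant_id", columns="condition",
                        values="percent_correct")
    cognitive = pd.read_csv(cfg.outdir / "scores" / "cognitive_measures.csv",
                            index_col="participant_id")
    cohort = pd.read_csv(cfg.outdir / "sim" / "cohort.csv", index_col="participant_id")
    demo = cohort[["age", "education", "ssq_speech", "ssq_spatial", "ssq_qualities"]]
    table = wide.join(cognitive).join(demo)
    table.columns.name = None
    return table


def stage_analyze(cfg: RunConfig) -> list:
    """Fence, descriptives, omnibus + pairwise tests, correlations, models."""
    out = cfg.outdir / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    table = build_measure_table(cfg)
    conditions = list(cfg.raw["design"]["conditions"])
    screen = [c for c in SCREEN_COLUMNS if c in table.columns]

    k = float(cfg.get("analysis", "fence_k", default=3.0))
    fenced, report = fence_adjust(table, k=k, columns=screen)
    report.to_frame().to_csv(out / "fence_report.csv", index=False)

    desc_rows = []
    for col in screen:
        mean, sd, lo, hi, skew, kurt = describe(fenced[col])
        desc_rows.append({"measure": col, "mean": mean, "sd": sd, "min": lo,
                          "max": hi, "skew": skew, "kurtosis": kurt})
    pd.DataFrame(desc_rows).to_csv(out / "descriptives.csv", index=False)

    groups = [fenced[c].dropna().to_numpy() for c in conditions]
    lev_f, lev_p = levene(groups, cfg.get("analysis", "levene_center", default="mean"))
    anova = welch_anova(groups)
    pd.DataFrame([{
        "levene_F": lev_f, "levene_p": lev_p,
        "welch_F": anova.F, "welch_df1": anova.df1,
        "welch_df2": anova.df2, "welch_p": anova.p,
    }]).to_csv(out / "anova.csv", index=False)
    pairwise_welch_bh(groups, conditions).to_csv(out / "pairwise.csv", index=False)

    corr_cols = [c for c in screen if not c.startswith(("age", "ssq"))]
    r, p = correlation_screen(fenced, corr_cols)
    r.to_csv(out / "correlations_r.csv")
    p.to_csv(out / "correlations_p.csv")
    pd.DataFrame([{
        "alpha": 0.05,
        "bonferroni_24": bonferroni_alpha(0.05, 24),
        "bonferroni_6": bonferroni_alpha(0.05, 6),
    }]).to_csv(out / "alpha_levels.csv", index=False)

    model_rows, diag_rows, audit_rows = [], [], []
    for cond in conditions:
        saturated = [c for c in SATURATED if c in fenced.columns]
        sel = purposeful_selection(
            fenced, cond, saturated, hypothesis_set=PREDICTORS,
            p_stay=float(cfg.get("analysis", "selection_p_stay", default=0.25)),
            delta_beta_max=float(cfg.get("analysis", "selection_delta_beta", default=0.20)),
            literal_direction=bool(cfg.get("analysis", "literal_direction", default=False)),
        )
        for rec in sel.audit:
            audit_rows.append({"condition": cond, **rec})
        fit = RestorationModel.from_dataframe(fenced, cond, PREDICTORS).fit()
        frame = fit.to_frame()
        frame.insert(0, "condition", cond)
        frame.insert(1, "predictor", frame.index)
        frame["r2"] = fit.rsquared
        frame["adj_r2"] = fit.rsquared_adj
        frame["model_F"] = fit.fvalue
        frame["model_p"] = fit.f_pvalue
        model_rows.append(frame)
        diag = fit.diagnostics()
        d = diag.to_frame()
        d.insert(0, "condition", cond)
        diag_rows.append(d)
    pd.concat(model_rows, ignore_index=True).to_csv(out / "models.csv", index=False)
    pd.concat(diag_rows, ignore_index=True).to_csv(out / "diagnostics.csv", index=False)
    pd.DataFrame(audit_rows).to_csv(out / "selection_audit.csv", index=False)
    return [out / f for f in (
        "fence_report.csv", "descriptives.csv", "anova.csv", "pairwise.csv",
        "correlations_r.csv", "correlations_p.csv", "alpha_levels.csv",
        "models.csv", "diagnostics.csv", "selection_audit.csv")]


def stage_power(cfg: RunConfig) -> list:
    out = cfg.outdir / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    p = cfg.raw.get("power", DEFAULT_CONFIG["power"])
    spec = PowerSpec(f2=p["f2"], alpha=p["alpha"], power=p["power"],
                     n_predictors=p["n_predictors"],
                     lambda_convention=p.get("lambda_convention", "total_n"))
    n = required_sample_size(spec)
    payload = {"required_n": n, "achieved_power": achieved_power(spec, n),
               "spec": p}
    with open(out / "power.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    return [out / "power.json"]


STAGES = [
    ("simulate", stage_simulate, ()),
    ("stimuli", stage_stimuli, ("simulate",)),
    ("score_transcripts", stage_score, ("simulate",)),
    ("score_cognitive", stage_cognitive, ("simulate",)),
    ("analyze", stage_analyze, ("score_transcripts", "score_cognitive")),
    ("power", stage_power, ()),
]


def run_pipeline(cfg: RunConfig, force: bool = False, stages=None) -> dict:
    """Execute the stages in dependency order; return the run manifest.

    The manifest lists every output file with its SHA-256 checksum, the
    stage parameters, seeds, and package version. Stages with all outputs
    already present are skipped (recorded as ``cached``) unless ``force``.
    """
    wanted = set(stages) if stages else {name for name, _, _ in STAGES}
    # pull in dependencies
    changed = True
    while changed:
        changed = False
        for name, _, deps in STAGES:
            if name in wanted:
                for d in deps:
                    if d not in wanted:
                        wanted.add(d)
                        changed = True

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.raw,
        "stages": {},
    }
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = cfg.outdir / "manifest.json"
    previous = {}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            previous = json.load(fh).get("stages", {})

    for name, fn, deps in STAGES:
        if name not in wanted:
            if name in previous:
                manifest["stages"][name] = previous[name]
            continue
        prior_files = [cfg.outdir / f for f in previous.get(name, {}).get("files", {})]
        if not force and prior_files and _stage_done(prior_files):
            entry = dict(previous[name])
            entry["cached"] = True
            manifest["stages"][name] = entry
            continue
        t0 = time.time()
        files = fn(cfg)
        manifest["stages"][name] = {
            "cached": False,
            "elapsed_s": round(time.time() - t0, 3),
            "files": {str(Path(f).relative_to(cfg.outdir)): _sha256(Path(f))
                      for f in files},
        }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
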