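"""End-to-end orchestration: simulate a cohort, preprocess the EMG,
run every analysis of the study chain, and render a results report.

The analysis sequence mirrors the study logic:

1. reverse-correlation kernels per participant, group-average kernels,
   band-wise group comparisons, and Kernel Distances to the combined
   reference kernel;
2. perceptual accuracy per participant, one-sample tests against chance
   per group, the group comparison with its JZS Bayes factor;
3. EMG window amplitudes; mixed ANOVA of Timing (Listening vs.
   Processing) x Muscle x Group; omnibus Muscle x Group on the target
   window; per-muscle Filter x Choice x Group ANOVAs and within-group
   follow-ups;
4. ZM_filter / CS_choice difference scores and Pearson correlations
   (Kernel Distance vs. accuracy, accuracy vs. AQ/EQ, ZM_filter vs.
   CS_choice per group).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as vbehavior
from . import emg as vemg
from . import revcorr as vrevcorr
from . import stats as vstats
from .emg import Epochs, PipelineConfig
from .simulate import (ASD, NT, Cohort, EmgGenParams, SessionDesign,
                       simulate_cohort)
from .stimgen import EqualizerParams

__all__ = [
    "RunConfig",
    "cohort_amplitudes",
    "analyze_cohort",
    "effect_flags",
    "write_dataset",
    "read_dataset",
    "write_results",
    "render_report",
]


@dataclass(frozen=True)
class RunConfig:
    """Bundled configuration for a full simulate -> analyze run."""

    seed: int = 0
    n_nt: int = 21
    n_asd: int = 20
    n_revcorr_trials: int = 600
    consistency: float = 0.75
    accuracy_target: float = 0.75
    alpha: float = 0.05
    prior_scale: float = 0.707
    equalizer: EqualizerParams = field(default_factory=EqualizerParams)
    design: SessionDesign = field(default_factory=SessionDesign)
    emg: EmgGenParams = field(default_factory=EmgGenParams)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, sub in (("equalizer", EqualizerParams),
                         ("design", SessionDesign),
                         ("pipeline", PipelineConfig)):
            if key in raw:
                kwargs[key] = sub(**raw.pop(key))
        if "emg" in raw:
            emg_raw = raw.pop("emg")
            for tup in ("carrier_band", "asd_relaxation", "epoch_span_ms"):
                if tup in emg_raw:
                    emg_raw[tup] = tuple(emg_raw[tup])
            kwargs["emg"] = EmgGenParams(**emg_raw)
        return cls(**raw, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["equalizer"] = asdict(self.equalizer)
        raw["emg"].pop("effects", None)  # effect list is code-defined
        Path(path).write_text(yaml.safe_dump(_jsonable(raw), sort_keys=False))

    def simulate(self, **overrides) -> Cohort:
        return simulate_cohort(
            seed=self.seed, n_nt=self.n_nt, n_asd=self.n_asd,
            eq_params=self.equalizer, design=self.design,
            emg_params=self.emg, n_revcorr_trials=self.n_revcorr_trials,
            consistency=self.consistency,
            accuracy_target=self.accuracy_target, **overrides)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def cohort_amplitudes(cohort: Cohort, cfg: PipelineConfig = PipelineConfig()
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the EMG pipeline for every participant in the cohort.

    Returns (amplitudes, rejection_log); amplitudes carries the group
    label of each participant alongside the per-trial window means.
    """
    fs = cohort.emg_params.fs
    times = vemg.epoch_times(fs, *cohort.emg_params.epoch_span_ms)
    frames, logs = [], []
    for pid, pdata in cohort.data.items():
        if pdata.emg is None:
            raise ValueError("cohort was simulated without EMG")
        epochs = Epochs(fs, times, pdata.emg,
                        pdata.behavior[["sentence_id", "filter", "choice"]])
        amps, log = vemg.process_epochs(epochs, cfg, participant=pid)
        amps.insert(1, "group", pdata.group)
        frames.append(amps)
        log["group"] = pdata.group
        logs.append(log)
    return pd.concat(frames, ignore_index=True), pd.DataFrame(logs)


def _timing_table(amplitudes: pd.DataFrame) -> pd.DataFrame:
    long = amplitudes.melt(
        id_vars=["participant", "group", "muscle"],
        value_vars=["mean_listening", "mean_processing"],
        var_name="timing", value_name="amplitude")
    long["timing"] = long["timing"].str.replace("mean_", "", regex=False)
    return long


def analyze_cohort(cohort: Cohort, config: RunConfig = RunConfig(),
                   amplitudes: pd.DataFrame | None = None) -> dict:
    """Full analysis chain on a (simulated or loaded) cohort."""
    alpha = config.alpha
    results: dict = {"seed": cohort.seed, "alpha": alpha}

    # ----- reverse correlation ------------------------------------------
    kernels: dict[str, vrevcorr.Kernel] = {}
    for pid, pdata in cohort.data.items():
        if pdata.revcorr is not None:
            kernels[pid] = vrevcorr.estimate_kernel(pdata.revcorr)
    if kernels:
        groups = cohort.participants.set_index("participant_id")["group"]
        nt_k = [kernels[p] for p in kernels if groups[p] == NT]
        asd_k = [kernels[p] for p in kernels if groups[p] == ASD]
        reference = vrevcorr.group_kernel(list(kernels.values()))
        results["kernels"] = kernels
        results["group_kernels"] = {NT: vrevcorr.group_kernel(nt_k),
                                    ASD: vrevcorr.group_kernel(asd_k)}
        results["band_comparisons"] = vrevcorr.compare_bands(nt_k, asd_k, alpha)
        results["kernel_distance"] = pd.DataFrame({
            "participant": list(kernels),
            "group": [groups[p] for p in kernels],
            "kernel_distance": [vrevcorr.kernel_distance(kernels[p], reference)
                                for p in kernels],
        })

    # ----- behavior ------------------------------------------------------
    acc_rows = []
    for pid, pdata in cohort.data.items():
        summary = vbehavior.perceptual_accuracy(pdata.behavior)
        acc_rows.append({"participant": pid, "group": pdata.group,
                         "accuracy": summary.accuracy,
                         "n_trials": summary.n_smileF + summary.n_unsmileF})
    accuracy = pd.DataFrame(acc_rows)
    results["accuracy"] = accuracy
    by_group = {g: accuracy.loc[accuracy["group"] == g, "accuracy"].to_numpy()
                for g in (NT, ASD)}
    results["chance_tests"] = {
        g: vbehavior.test_above_chance(v) for g, v in by_group.items()}
    group_t = vstats.two_sample_t(by_group[NT], by_group[ASD])
    results["accuracy_group_t"] = group_t
    results["accuracy_bf"] = vstats.jzs_bf_ttest(
        group_t.t, len(by_group[NT]), len(by_group[ASD]),
        prior_scale=config.prior_scale)

    # ----- EMG amplitudes and ANOVAs ------------------------------------
    if amplitudes is None and all(p.emg is not None
                                  for p in cohort.data.values()):
        amplitudes, rejection = cohort_amplitudes(cohort, config.pipeline)
        results["rejection_log"] = rejection
    if amplitudes is not None:
        results["amplitudes"] = amplitudes
        results["anova_timing"] = vstats.rm_anova(
            _timing_table(amplitudes), "amplitude", "participant",
            within=["timing", "muscle"], between="group")
        # post-hoc for the Timing x Group interaction: paired Listening vs.
        # Processing within each group, Bonferroni over the two groups
        posthoc = {}
        cell = amplitudes.groupby(["group", "participant"], observed=True)[
            ["mean_listening", "mean_processing"]].mean()
        for g in (NT, ASD):
            sub = cell.loc[g]
            res = vstats.paired_t(sub["mean_listening"],
                                  sub["mean_processing"])
            corrected = float(vstats.bonferroni([res.p], 2)[0])
            posthoc[g] = vstats.TTestResult(res.t, res.df, res.p,
                                            "paired", corrected)
        results["posthoc_timing"] = posthoc
        results["anova_target_omnibus"] = vstats.rm_anova(
            amplitudes, "mean_target", "participant",
            within=["muscle"], between="group")
        for muscle in vemg.MUSCLES:
            sub = amplitudes[amplitudes["muscle"] == muscle]
            results[f"anova_{muscle}"] = vstats.rm_anova(
                sub, "mean_target", "participant",
                within=["filter", "choice"], between="group")
            for grp in (NT, ASD):
                gsub = sub[sub["group"] == grp]
                results[f"anova_{muscle}_{grp.lower()}"] = vstats.rm_anova(
                    gsub, "mean_target", "participant",
                    within=["filter", "choice"])
        diffs = vemg.difference_scores(amplitudes)
        diffs = diffs.merge(cohort.participants,
                            left_on="participant",
                            right_on="participant_id")
        results["difference_scores"] = diffs

    # ----- correlations --------------------------------------------------
    corr: dict[str, vstats.PearsonResult] = {}

    def safe_corr(name, x, y):
        try:
            corr[name] = vbehavior.correlate(x, y)
        except ValueError:  # too few or constant values (tiny cohorts)
            pass

    if "kernel_distance" in results:
        kd = results["kernel_distance"].merge(
            accuracy, on=["participant", "group"])
        safe_corr("kernel_distance_vs_accuracy",
                  kd["kernel_distance"], kd["accuracy"])
        for g in (NT, ASD):
            sub = kd[kd["group"] == g]
            safe_corr(f"kernel_distance_vs_accuracy_{g.lower()}",
                      sub["kernel_distance"], sub["accuracy"])
    cov = accuracy.merge(cohort.participants, left_on="participant",
                         right_on="participant_id")
    safe_corr("accuracy_vs_aq", cov["accuracy"], cov["aq"])
    safe_corr("accuracy_vs_eq", cov["accuracy"], cov["eq"])
    if "difference_scores" in results:
        for g in (NT, ASD):
            sub = results["difference_scores"]
            sub = sub[sub["group"] == g]
            safe_corr(f"zm_filter_vs_cs_choice_{g.lower()}",
                      sub["zm_filter"], sub["cs_choice"])
    results["correlations"] = corr
    return results


def pattern_flags(seed: int, config: RunConfig = RunConfig(),
                  null_effects: bool = False) -> dict[str, bool]:
    """Simulate one cohort (EMG + behavior only) and return the boolean
    motor-resonance pattern flags — the minimal path for power/size
    studies over many seeded cohorts."""
    from dataclasses import replace as _replace

    cfg = _replace(config, seed=seed)
    cohort = cfg.simulate(include_revcorr=False, null_effects=null_effects)
    amps, _ = cohort_amplitudes(cohort, cfg.pipeline)
    results: dict = {"amplitudes": amps}
    results["anova_timing"] = vstats.rm_anova(
        _timing_table(amps), "amplitude", "participant",
        within=["timing", "muscle"], between="group")
    for muscle in vemg.MUSCLES:
        sub = amps[amps["muscle"] == muscle]
        for grp in (NT, ASD):
            results[f"anova_{muscle}_{grp.lower()}"] = vstats.rm_anova(
                sub[sub["group"] == grp], "mean_target", "participant",
                within=["filter", "choice"])
    return effect_flags(results, cfg.alpha)


def effect_flags(results: dict, alpha: float = 0.05) -> dict[str, bool]:
    """Boolean summary of the qualitative motor-resonance pattern."""
    flags = {}
    flags["nt_zm_filter"] = results["anova_zm_nt"]["filter"].p < alpha
    flags["nt_cs_choice"] = results["anova_cs_nt"]["choice"].p < alpha
    timing = results["anova_timing"]
    amp = results["amplitudes"]
    cell = amp.groupby(["group", "participant"], observed=True)[
        ["mean_listening", "mean_processing"]].mean()
    decline = (cell["mean_processing"] - cell["mean_listening"]).groupby("group").mean()
    flags["asd_relaxation"] = bool(
        timing["timing * group"].p < alpha and decline[ASD] < decline[NT])
    for muscle in vemg.MUSCLES:
        tab = results[f"anova_{muscle}_asd"]
        flags[f"asd_{muscle}_filter"] = tab["filter"].p < alpha
        flags[f"asd_{muscle}_choice"] = tab["choice"].p < alpha
    flags["pattern_recovered"] = bool(
        flags["nt_zm_filter"] and flags["nt_cs_choice"]
        and flags["asd_relaxation"]
        and not any(flags[f"asd_{m}_{f}"] for m in vemg.MUSCLES
                    for f in ("filter", "choice")))
    return flags


# --------------------------------------------------------------------------
# dataset I/O


def _assemble_recording(pdata, emg_params: EmgGenParams,
                        design: SessionDesign, rng: np.random.Generator
                        ) -> vemg.EMGRecording:
    """Place simulated epochs into a continuous recording with tonus-level
    carrier noise between trials."""
    from .simulate import band_limited_noise

    fs = emg_params.fs
    tmin, tmax = emg_params.epoch_span_ms
    n_samp = pdata.emg.shape[-1]
    spacing = int(np.ceil(design.trial_spacing_ms * fs / 1000.0))
    n_trials = pdata.emg.shape[0]
    total = spacing * n_trials + int(fs)
    channels = {}
    gap_noise = band_limited_noise(total, fs, emg_params.carrier_band, rng,
                                   shape=(2,), dtype=np.float32)
    onsets_samples = np.arange(n_trials) * spacing + int(round(1.0 * fs))
    for j, m in enumerate(vemg.MUSCLES):
        tr = gap_noise[j] * emg_params.baseline_tonus[m]
        for i, onset in enumerate(onsets_samples):
            start = onset + int(round(tmin * fs / 1000.0))
            tr[start:start + n_samp] = pdata.emg[i, j]
        channels[m] = tr
    events = pdata.behavior[["sentence_id", "filter", "choice"]].copy()
    events.insert(0, "onset_ms", onsets_samples / fs * 1000.0)
    return vemg.EMGRecording(fs, channels, events)


def write_dataset(cohort: Cohort, path: str | Path, force: bool = False,
                  emg_format: str = "wav") -> Path:
    """Serialize a cohort: participants.csv plus one directory per
    participant (revcorr.csv, behavior.csv, events.csv, emg.wav|csv,
    ground_truth.json)."""
    from scipy.io import wavfile

    path = Path(path)
    if path.exists() and any(path.iterdir()) and not force:
        raise FileExistsError(f"{path} exists; use force=True to overwrite")
    path.mkdir(parents=True, exist_ok=True)
    cohort.participants.to_csv(path / "participants.csv", index=False)
    meta = {"seed": cohort.seed, "fs": cohort.emg_params.fs,
            "epoch_span_ms": list(cohort.emg_params.epoch_span_ms),
            "emg_format": emg_format}
    (path / "meta.json").write_text(json.dumps(_jsonable(meta), indent=2))
    for idx, (pid, pdata) in enumerate(cohort.data.items()):
        pdir = path / pid
        pdir.mkdir(exist_ok=True)
        pdata.behavior.to_csv(pdir / "behavior.csv", index=False)
        if pdata.revcorr is not None:
            pdata.revcorr.to_frame().to_csv(pdir / "revcorr.csv", index=False)
        (pdir / "ground_truth.json").write_text(
            json.dumps(_jsonable(pdata.ground_truth), indent=2))
        if pdata.emg is not None:
            rng = np.random.default_rng([cohort.seed, idx, 2**20])
            rec = _assemble_recording(pdata, cohort.emg_params,
                                      cohort.design, rng)
            rec.events.to_csv(pdir / "events.csv", index=False)
            if emg_format == "wav":
                stacked = np.stack([rec.channels[m] for m in vemg.MUSCLES],
                                   axis=1).astype(np.float32)
                wavfile.write(pdir / "emg.wav", int(rec.fs), stacked)
            else:
                df = pd.DataFrame({
                    "t_ms": np.arange(rec.n_samples) / rec.fs * 1000.0,
                    "zm_uv": rec.channels["zm"],
                    "cs_uv": rec.channels["cs"],
                })
                df.to_csv(pdir / "emg.csv", index=False)
    return path


def read_dataset(path: str | Path) -> Cohort:
    """Load a serialized cohort; EMG is re-epoched from the continuous
    recordings using the stored event markers."""
    from scipy.io import wavfile

    path = Path(path)
    participants = pd.read_csv(path / "participants.csv")
    meta = json.loads((path / "meta.json").read_text())
    fs = float(meta["fs"])
    tmin, tmax = meta["epoch_span_ms"]
    data = {}
    from .simulate import ParticipantData, RevcorrSession
    from .stimgen import FrequencyGrid

    for row in participants.itertuples():
        pid = row.participant_id
        pdir = path / pid
        behav = pd.read_csv(pdir / "behavior.csv")
        truth = json.loads((pdir / "ground_truth.json").read_text())
        revc = None
        if (pdir / "revcorr.csv").exists():
            rc = pd.read_csv(pdir / "revcorr.csv")
            bands = np.sort(rc["band_hz"].unique())
            wide = rc.pivot(index="trial_id", columns="band_hz",
                            values="gain_db").sort_index()
            choices = rc.drop_duplicates("trial_id").sort_values(
                "trial_id")["choice"].to_numpy()
            revc = RevcorrSession(FrequencyGrid(bands),
                                  wide.to_numpy(), choices)
        emg_epochs = None
        if (pdir / "emg.wav").exists() or (pdir / "emg.csv").exists():
            events = pd.read_csv(pdir / "events.csv")
            if (pdir / "emg.wav").exists():
                _, stacked = wavfile.read(pdir / "emg.wav")
                channels = {m: stacked[:, j].astype(np.float32)
                            for j, m in enumerate(vemg.MUSCLES)}
            else:
                df = pd.read_csv(pdir / "emg.csv")
                channels = {"zm": df["zm_uv"].to_numpy(),
                            "cs": df["cs_uv"].to_numpy()}
            rec = vemg.EMGRecording(fs, channels, events)
            emg_epochs = vemg.epoch(rec, tmin, tmax).data.astype(np.float32)
        data[pid] = ParticipantData(pid, row.group, row.aq, row.eq,
                                    revc, behav, emg_epochs, truth)
    return Cohort(participants, data, EmgGenParams(), EqualizerParams(),
                  SessionDesign(), int(meta["seed"]))


# --------------------------------------------------------------------------
# results serialization and report


def _stat_dict(obj):
    if isinstance(obj, vstats.AnovaTable):
        return {r.effect: {"F": r.F, "df": [r.df_num, r.df_den], "p": r.p,
                           "partial_eta_sq": r.partial_eta_sq} for r in obj}
    if isinstance(obj, vstats.TTestResult):
        out = {"t": obj.t, "df": obj.df, "p": obj.p, "kind": obj.kind}
        if obj.corrected_p is not None:
            out["corrected_p"] = obj.corrected_p
        return out
    if isinstance(obj, vstats.BayesFactorResult):
        return {"bf10": obj.bf10, "prior_scale": obj.prior_scale,
                "integration_error": obj.integration_error}
    if isinstance(obj, vstats.PearsonResult):
        return {"r": obj.r, "df": obj.df, "t": obj.t, "p": obj.p}
    return obj


def write_results(results: dict, outdir: str | Path) -> Path:
    """Write analysis outputs: CSV tables, a stats JSON, and report.md."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stats_json: dict = {"seed": results.get("seed"),
                        "alpha": results.get("alpha")}
    for key, val in results.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(outdir / f"{key}.csv", index=False)
        elif isinstance(val, (vstats.AnovaTable, vstats.TTestResult,
                              vstats.BayesFactorResult)):
            stats_json[key] = _stat_dict(val)
        elif isinstance(val, dict) and key in ("chance_tests", "correlations",
                                               "posthoc_timing"):
            stats_json[key] = {k: _stat_dict(v) for k, v in val.items()}
    if "kernels" in results:
        vrevcorr.kernels_to_frame(results["kernels"]).to_csv(
            outdir / "kernels.csv", index=False)
    if "band_comparisons" in results:
        pd.DataFrame([vars(b) for b in results["band_comparisons"]]).to_csv(
            outdir / "band_comparisons.csv", index=False)
    (outdir / "stats.json").write_text(
        json.dumps(_jsonable(stats_json), indent=2))
    (outdir / "report.md").write_text(render_report(results))
    return outdir


def _fmt_anova(table: vstats.AnovaTable) -> str:
    lines = []
    for r in table:
        star = " *" if r.p < 0.05 else ""
        lines.append(f"- {r.effect}: F({r.df_num},{r.df_den}) = {r.F:.2f}, "
                     f"p = {r.p:.3g}, partial eta^2 = {r.partial_eta_sq:.3f}{star}")
    return "\n".join(lines)


def render_report(results: dict) -> str:
    """Markdown report following the study's results structure."""
    out = ["# Simulated study report", ""]
    out.append(f"Seed: {results.get('seed')}  |  alpha = {results.get('alpha')}")
    if "band_comparisons" in results:
        sig = [b for b in results["band_comparisons"] if b.significant]
        out += ["", "## Representation of vocal smile",
                f"Bands with a significant NT/ASD kernel difference "
                f"(uncorrected): {[round(b.band_hz) for b in sig] or 'none'}"]
    if "accuracy" in results:
        acc = results["accuracy"].groupby("group")["accuracy"].mean()
        out += ["", "## Perceptual accuracy"]
        for g, v in acc.items():
            ct = results["chance_tests"][g]
            out.append(f"- {g}: mean accuracy {v:.3f}; vs. chance "
                       f"t({ct.df}) = {ct.t:.2f}, p = {ct.p:.3g}")
        gt = results["accuracy_group_t"]
        bf = results["accuracy_bf"]
        out.append(f"- group difference: t({gt.df}) = {gt.t:.2f}, "
                   f"p = {gt.p:.3g}; BF10 = {bf.bf10:.3f}")
    if "anova_timing" in results:
        out += ["", "## Muscular activity during listening and processing",
                _fmt_anova(results["anova_timing"])]
        if "posthoc_timing" in results:
            out.append("Post-hoc Listening vs. Processing (Bonferroni m=2):")
            for g, res in results["posthoc_timing"].items():
                out.append(f"- {g}: t({res.df}) = {res.t:.2f}, "
                           f"p_corr = {res.corrected_p:.3g}")
        out += ["", "## Target window (2900-3400 ms), omnibus",
                _fmt_anova(results["anova_target_omnibus"])]
        for muscle, name in (("zm", "Zygomaticus major"),
                             ("cs", "Corrugator supercilii")):
            out += ["", f"## {name}", _fmt_anova(results[f"anova_{muscle}"])]
            for grp in (NT, ASD):
                out += [f"", f"### {grp}",
                        _fmt_anova(results[f"anova_{muscle}_{grp.lower()}"])]
    if "correlations" in results:
        out += ["", "## Correlations"]
        for name, res in results["correlations"].items():
            out.append(f"- {name}: r({res.df}) = {res.r:.2f}, "
                       f"t = {res.t:.2f}, p = {res.p:.3g}")
    out.append("")
    return "\n".join(out)
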