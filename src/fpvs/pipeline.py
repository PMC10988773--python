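"""End-to-end simulation and analysis: session plans -> recordings -> tables.

`simulate_dataset` writes a synthetic multi-participant dataset (fixture
containers + plan sidecars + manifest) and `analyze_dataset` runs the full
preprocessing and frequency-domain analysis on any dataset laid out the
same way, producing tidy TSV tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .config import RunConfig
from .design import SequencePlan, demo_stimulus_sets, plan_session
from .errors import ValidationError
from .preprocess import average_epochs, preprocess
from .report import ROI, grand_average, roi_average, score_behavior, \
    individual_significance
from .spectral import AmplitudeSpectrum, amplitude_spectrum
from .stats import NoiseWindowSpec, candidate_harmonics, \
    select_significant_harmonics, sum_harmonics, summed_amplitude_z
from .synth import NoiseSpec, default_base_response, default_oddball_response, \
    synthesize_recording

CELL_KEY = ("task", "discrimination", "control_type")


def simulate_keypresses(plan: SequencePlan, config: RunConfig,
                        seed: int) -> list[float]:
    """Simulate a participant's keypresses for one sequence's task events.

    Go events are answered with probability ``p_hit`` at a Gaussian reaction
    time; no-go events draw a false-alarm press with probability
    ``p_false_alarm``.
    """
    rng = np.random.default_rng(seed)
    presses = []
    for ev in plan.events:
        respond = rng.random() < (config.p_hit if ev.is_go else config.p_false_alarm)
        rt = float(np.clip(rng.normal(config.rt_mean_s, config.rt_sd_s),
                           config.response_window_s[0] + 0.01,
                           config.response_window_s[1] - 0.01))
        if respond:
            presses.append(ev.onset_s + rt)
    return presses


def simulate_dataset(out_dir: str | Path, config: RunConfig | None = None,
                     noiseless: bool = False) -> dict:
    """Write a synthetic dataset for ``config.n_participants`` participants.

    Layout: ``sub-XX/seq-YY.{f32,json}`` recordings, ``sub-XX/seq-YY.plan.json``
    sidecars, per-sequence events TSV, and a ``manifest.json`` tying
    everything to the configuration and per-sequence seeds.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    oddball = default_oddball_response(config.oddball_amps)
    base = default_base_response(config.base_amps)
    noise = NoiseSpec(0.0, 0.0, 0.0, white_scale=0.0) if noiseless else NoiseSpec(
        pink_exponent=config.pink_exponent, pink_scale=config.pink_scale,
        alpha_amp=config.alpha_amp, white_scale=config.white_scale,
    )
    manifest = {"config": _config_doc(config), "participants": [], "noiseless": noiseless}
    for p in range(config.n_participants):
        sub = f"sub-{p + 1:02d}"
        sub_dir = out / sub
        sub_dir.mkdir(exist_ok=True)
        p_seed = int(root.generate_state(1 + p)[-1]) % (2**31)
        session = plan_session(
            demo_stimulus_sets(seed=p_seed),
            n_reps=config.n_reps,
            task_order=config.task_order,
            seed=p_seed,
            n_events=config.n_task_events,
            duration_s=config.duration_s,
            f_base=config.f_base_hz,
            oddball_every=config.oddball_every,
            fade_in_s=config.fade_in_s,
            fade_out_s=config.fade_out_s,
        )
        seqs = []
        seq_seeds = np.random.SeedSequence(p_seed).generate_state(
            2 * len(session.sequences))
        for i, plan in enumerate(session.sequences):
            stem = sub_dir / f"seq-{i + 1:02d}"
            rec_seed = int(seq_seeds[2 * i]) % (2**31)
            press_seed = int(seq_seeds[2 * i + 1]) % (2**31)
            rec = synthesize_recording(plan, oddball, base, noise,
                                       fs_hz=config.fs_hz, seed=rec_seed)
            fio.write_recording(stem, rec)
            fio.write_plan(stem.with_suffix(".plan.json"), plan)
            fio.write_events_tsv(stem.with_suffix(".events.tsv"), plan.events)
            presses = simulate_keypresses(plan, config, press_seed)
            seqs.append({
                "stem": f"{sub}/seq-{i + 1:02d}",
                "task": plan.task,
                "discrimination": plan.discrimination,
                "control_type": plan.control_type,
                "seed": rec_seed,
                "keypresses": presses,
            })
        manifest["participants"].append({"id": sub, "seed": p_seed, "sequences": seqs})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _config_doc(config: RunConfig) -> dict:
    doc = asdict(config)
    for k, v in doc.items():
        if isinstance(v, tuple):
            doc[k] = list(v)
    return doc


def analyze_dataset(data_dir: str | Path, config: RunConfig | None = None,
                    out_dir: str | Path | None = None) -> dict:
    """Run the full frequency-domain analysis over a simulated/loaded dataset.

    Per participant and design cell: sequences are preprocessed, averaged in
    the time domain, Fourier-transformed and ROI-averaged.  Harmonic
    significance is established once on the grand-averaged spectra (oddball:
    mean of LROI and RROI; base rate: MO), then per-participant summed
    baseline-corrected amplitudes and individual z-scores are tabulated.

    Returns a dict with the tidy tables; writes TSVs when ``out_dir`` given.
    """
    config = config or RunConfig()
    data = Path(data_dir)
    manifest_path = data / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"no manifest.json in {data}")
    manifest = json.loads(manifest_path.read_text())
    if not manifest.get("participants"):
        raise ValidationError("manifest lists no participants")

    rois = {name: ROI(name, tuple(chs)) for name, chs in config.rois.items()}
    oddball_roi_names = ["LROI", "RROI"]

    # participant -> cell -> {roi_name: 1-channel spectrum}
    cell_spectra: dict[str, dict[tuple, dict[str, object]]] = {}
    behavior_rows = []
    for part in manifest["participants"]:
        epochs_by_cell: dict[tuple, list] = {}
        for seq in part["sequences"]:
            rec = fio.read_recording(data / seq["stem"])
            epoch = preprocess(
                rec, lo_hz=config.lo_hz, hi_hz=config.hi_hz,
                pre_s=config.pre_s, post_s=config.post_s,
                target_fs=config.target_fs, cycle_s=config.cycle_s,
                stim_s=config.duration_s,
            )
            cell = (seq["task"], seq["discrimination"], seq["control_type"])
            epochs_by_cell.setdefault(cell, []).append(epoch)
            plan = fio.read_plan((data / seq["stem"]).with_suffix(".plan.json"))
            score = score_behavior(plan.events, seq.get("keypresses", []),
                                   window=config.response_window_s)
            behavior_rows.append({
                "participant": part["id"], "sequence": seq["stem"],
                "task": seq["task"], "discrimination": seq["discrimination"],
                "control_type": seq["control_type"],
                "n_go": score.n_go, "n_nogo": score.n_nogo,
                "hits": score.hits, "false_alarms": score.false_alarms,
                "hit_rate": score.hit_rate, "fa_rate": score.fa_rate,
                "mean_rt_s": score.mean_rt_s,
            })
        cells = {}
        for cell, epochs in epochs_by_cell.items():
            spectrum = amplitude_spectrum(average_epochs(epochs))
            cells[cell] = {name: roi_average(spectrum, roi)
                           for name, roi in rois.items()}
        cell_spectra[part["id"]] = cells

    # group-level harmonic selection on grand averages
    def grand(roi_names: list[str]):
        pooled = [
            spec
            for cells in cell_spectra.values()
            for by_roi in cells.values()
            for name, spec in by_roi.items()
            if name in roi_names
        ]
        return grand_average([
            AmplitudeSpectrum(amps=s.amps, freqs=s.freqs, df_hz=s.df_hz,
                              channel_names=["pooled"]) for s in pooled
        ])

    z_spec = NoiseWindowSpec.zscore_default()
    oddball_f = config.f_base_hz / config.oddball_every
    oddball_candidates = candidate_harmonics(
        oddball_f, config.f_base_hz, config.oddball_f_max_hz)
    base_candidates = candidate_harmonics(
        config.f_base_hz, None, config.base_f_max_hz, exclude_base=False)
    grand_oddball = grand(oddball_roi_names)
    grand_base = grand(["MO"])
    oddball_harmonics = select_significant_harmonics(
        grand_oddball, oddball_candidates, z_spec, config.z_group)
    base_harmonics = select_significant_harmonics(
        grand_base, base_candidates, z_spec, config.z_group)

    rows = []
    for pid, cells in cell_spectra.items():
        for cell, by_roi in cells.items():
            for roi_name, spec in by_roi.items():
                harmonics = base_harmonics if roi_name == "MO" else oddball_harmonics
                if not harmonics:
                    continue
                summary = sum_harmonics(spec, harmonics, z_spec=z_spec)
                z = summed_amplitude_z(spec, harmonics, z_spec=z_spec,
                                       method=config.individual_z_method)
                rows.append({
                    "participant": pid, "task": cell[0],
                    "discrimination": cell[1], "control_type": cell[2],
                    "roi": roi_name,
                    "summed_amp": summary.summed_corrected_amp,
                    "z": z,
                })
    results = pd.DataFrame(rows).sort_values(
        ["participant", "roi", "task", "discrimination", "control_type"]
    ).reset_index(drop=True)

    results["significant"] = results["z"] > config.z_individual
    oddball_results = results[results["roi"].isin(oddball_roi_names)]
    summary_counts = (
        individual_significance(oddball_results, config.z_individual)[1]
        if len(oddball_results) else {}
    )

    group_summary = (
        results.groupby(["roi", "task", "discrimination", "control_type"])
        .agg(mean_summed_amp=("summed_amp", "mean"),
             sd_summed_amp=("summed_amp", "std"),
             n_significant=("significant", "sum"),
             n=("participant", "nunique"))
        .reset_index()
    )
    behavior = pd.DataFrame(behavior_rows)

    out = {
        "individual_results": results,
        "group_summary": group_summary,
        "behavior": behavior,
        "harmonics": {"oddball": oddball_harmonics, "base": base_harmonics},
        "significance_summary": summary_counts,
    }
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        fio.write_table(out_path / "individual_results.tsv", results)
        fio.write_table(out_path / "group_summary.tsv", group_summary)
        fio.write_table(out_path / "behavior.tsv", behavior)
        run_manifest = {
            "config": _config_doc(config),
            "harmonics": out["harmonics"],
            "significance_summary": summary_counts,
            "rois": {n: list(r.channels) for n, r in rois.items()},
        }
        (out_path / "run_manifest.json").write_text(
            json.dumps(run_manifest, indent=1, sort_keys=True))
    return out
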