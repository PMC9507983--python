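"""End-to-end synthetic analysis: simulate -> preprocess -> entrain ->
surrogate -> time course -> behaviour -> report.

Every stage draws its randomness from child seeds of ``config.seed``, so a
rerun with the same configuration reproduces every output file byte for byte.
Outputs are tidy CSVs and JSON summaries plus an ITC spectrum figure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour as beh
from . import entrain, preprocess, simulate, streams, timecourse
from .io import RunConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "analyse_participant"]


def analyse_participant(
    stream: streams.SpeechStream, config: RunConfig, participant_seed: int,
    participant_id: str = "",
) -> dict:
    """Simulate and analyse one participant; returns summaries and bundle series."""
    eeg_cfg = simulate.SyntheticEEGConfig(
        sampling_rate=config.sampling_rate,
        n_channels=config.n_channels,
        roi_channels=config.roi_channels,
        kappa_word_start=config.kappa_word_start,
        kappa_word_end=config.kappa_word_end,
        kappa_syllable=config.kappa_syllable,
        word_amp=config.word_amp,
        syllable_amp=config.syllable_amp,
        noise_sigma=config.noise_sigma,
        words_per_epoch=config.words_per_epoch,
        seed=participant_seed,
    )
    rec, truth = simulate.simulate_recording(stream, eeg_cfg)
    roi = rec.meta["roi_channels"]
    if config.apply_filter:
        rec = preprocess.filter_recording(rec, config.band, config.notch)
    rec = preprocess.rereference_mastoids(rec)

    word_dur = 3 * config.syllable_duration
    epochs = preprocess.epoch_by_words(
        rec, stream.word_onsets, config.words_per_epoch, word_dur
    )
    epochs = preprocess.reject_artifacts(epochs, config.ptp_threshold, roi)

    summary = entrain.participant_summary(
        epochs, roi, participant_id,
        config.word_freq, config.syllable_freq, config.freq_range,
    )
    surr = entrain.surrogate_itc(
        rec, stream.word_onsets, config.jitter_range_ms,
        seed=participant_seed + 1,
        words_per_epoch=config.words_per_epoch, word_duration=word_dur,
        peak_to_peak_threshold=config.ptp_threshold,
        freq_range=config.freq_range, artifact_channels=roi,
    )
    surr_word = entrain.roi_average(
        entrain.extract_frequency(surr.itc, config.word_freq), roi, surr.itc.ch_names
    )
    surr_syll = entrain.roi_average(
        entrain.extract_frequency(surr.itc, config.syllable_freq), roi, surr.itc.ch_names
    )

    series = timecourse.bundle_itc_series(
        epochs, roi, participant_id, config.bundle_size,
        config.word_freq, config.syllable_freq, config.freq_range,
    )
    surr_epochs = preprocess.epoch_by_words(
        rec, surr.jittered_onsets, config.words_per_epoch, word_dur
    )
    surr_epochs = preprocess.reject_artifacts(surr_epochs, config.ptp_threshold, roi)
    surr_series = timecourse.bundle_itc_series(
        surr_epochs, roi, participant_id, config.bundle_size,
        config.word_freq, config.syllable_freq, config.freq_range,
    )
    return dict(
        summary=summary,
        surrogate_word=surr_word,
        surrogate_syllable=surr_syll,
        series=series,
        surrogate_series=surr_series,
        itc_spectrum=entrain.compute_itc(epochs, config.freq_range),
        surrogate_spectrum=surr.itc,
        roi=roi,
        truth=truth,
    )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic study and write reports under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    lexicon = streams.build_lexicon(config.lexicon_version)
    stream = streams.generate_stream(
        lexicon, config.reps_per_word, config.syllable_duration,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    streams.write_events_tsv(stream, out / "exposure_events.tsv")

    results = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        res = analyse_participant(
            stream, config, participant_seed=int(rng.integers(0, 2**31 - 1)),
            participant_id=pid,
        )
        results.append(res)
        logger.info("pipeline: analysed %s", pid)

    summaries = pd.DataFrame(
        [
            dict(
                participant_id=r["summary"].participant_id,
                itc_word=r["summary"].itc_word,
                itc_syllable=r["summary"].itc_syllable,
                wli=r["summary"].wli,
                surrogate_itc_word=r["surrogate_word"],
                surrogate_itc_syllable=r["surrogate_syllable"],
            )
            for r in results
        ]
    )
    summaries.to_csv(out / "entrainment_summaries.csv", index=False)

    report: dict = {"config": dataclasses.asdict(config)}
    if len(summaries) >= 3:
        for band_name in ("word", "syllable"):
            cmp = entrain.compare_actual_surrogate(
                summaries[f"itc_{band_name}"], summaries[f"surrogate_itc_{band_name}"]
            )
            report[f"actual_vs_surrogate_{band_name}"] = dataclasses.asdict(cmp)

    series = pd.concat([r["series"] for r in results], ignore_index=True)
    surr_series = pd.concat([r["surrogate_series"] for r in results], ignore_index=True)
    series.to_csv(out / "bundle_series.csv", index=False)
    surr_series.to_csv(out / "surrogate_bundle_series.csv", index=False)

    kept = timecourse.exclude_sparse_bundles(series, config.missing_threshold)
    lmm_report = {}
    for response in ("wli", "itc_word", "itc_syllable"):
        fit = timecourse.fit_learning_lmm(kept, response)
        lmm_report[response] = dict(
            formula=fit.formula, method=fit.method,
            estimate=fit.slope(), se=float(fit.term("bundle")["se"]),
            F=float(fit.term("bundle")["F"]), p=float(fit.term("bundle")["p"]),
            n_obs=fit.n_obs, n_groups=fit.n_groups, singular=fit.singular,
        )
    report["learning_lmm"] = lmm_report

    # restrict both series to the (participant, bundle) cells present in each
    common = kept[["participant_id", "bundle"]].merge(
        surr_series, on=["participant_id", "bundle"]
    )
    actual_common = common[["participant_id", "bundle"]].merge(
        kept, on=["participant_id", "bundle"]
    )
    surr_fit = timecourse.surrogate_timecourse(
        actual_common[["participant_id", "bundle", "itc_word"]],
        common[["participant_id", "bundle", "itc_word"]],
    )
    report["surrogate_timecourse_itc_word"] = dict(
        interaction=float(surr_fit.term("bundle:datatype")["estimate"]),
        p=float(surr_fit.term("bundle:datatype")["p"]),
    )

    # behaviour
    beh_cfg = simulate.BehaviourSimConfig(
        n_participants=config.n_participants,
        learning_strength=config.learning_strength,
        mode=config.mode,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    tables = simulate.simulate_behaviour(beh_cfg, lexicon)
    rating_scores = beh.score_rating(tables.rating)
    afc = beh.score_afc(tables.afc)
    detection = beh.score_detection(
        tables.detection_targets, tables.detection_presses, mode=tables.mode
    )
    scores = rating_scores.merge(afc.scores, on="participant_id").merge(
        detection, on="participant_id"
    )
    scores.to_csv(out / "behavioural_scores.csv", index=False)
    report["behaviour"] = dict(
        mean_rating_score=float(rating_scores["rating_score"].mean()),
        mean_afc_accuracy=afc.mean_accuracy,
        afc_t=afc.t, afc_p=afc.p,
        mean_hit_rate=float(detection["hit_rate"].mean()),
        mean_normalised_fa=float(detection["normalised_fa"].mean()),
        mean_rt_priming=float(detection["rt_priming"].mean()),
    )

    if len(summaries) >= 3:
        corr = entrain.correlate_entrainment_behaviour(summaries, scores)
        corr.to_csv(out / "entrainment_behaviour_correlations.csv", index=False)

    _plot_itc(results, config, out / "itc_spectrum.png")

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _plot_itc(results: list[dict], config: RunConfig, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for kind, color in (("itc_spectrum", "tab:blue"), ("surrogate_spectrum", "tab:gray")):
        spectra = []
        for r in results:
            itc = r[kind]
            roi_idx = [i for i, c in enumerate(itc.ch_names) if c in set(r["roi"])]
            spectra.append(itc.values[roi_idx].mean(axis=0))
        freqs = results[0][kind].bin_frequencies
        mean = np.mean(spectra, axis=0)
        label = "actual" if kind == "itc_spectrum" else "surrogate"
        ax.plot(freqs, mean, color=color, label=label)
    for f, name in ((1 / (3 * config.syllable_duration), "word"),
                    (1 / config.syllable_duration, "syllable")):
        ax.axvline(f, ls=":", color="k", lw=0.8)
        ax.text(f, ax.get_ylim()[1], name, ha="center", va="bottom", fontsize=8)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("ITC (ROI mean)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
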