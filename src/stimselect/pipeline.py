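"""End-to-end orchestration: simulate -> preprocess -> cluster -> syllables
-> selectivity, with per-stage derived seeds, persisted intermediates and a
machine-readable summary.

One :func:`run_pipeline` call reproduces the full synthetic study: a
selective (TIS-like) and a non-selective (biphasic-like) regime are
simulated per subject, every stage writes its outputs as plain CSV/JSON
(plus figures), and the summary collects AMI per subject, selectivity per
configuration and the group comparison.  Identical config and seed give a
byte-identical summary.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import embedding, preprocess, selectivity, syllables, synthgen
from .io import read_dlc_csv, read_sweep_log, DLCFormatError, SweepLogError

__all__ = ["RunConfig", "derive_seed", "run_pipeline", "validate_inputs"]


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 so stages rerun reproducibly."""
    return (int(seed) + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Configuration for a full synthetic study run."""

    outdir: str = "stimselect_run"
    seed: int = 0
    n_subjects: int = 2
    n_configs: int = 8
    on_s: float = 5.0
    off_s: float = 5.0
    fps: float = 60.0
    dropout_rate: float = 0.02
    noise_px: float = 2.0
    nonselective_motifs: int = 2
    likelihood_threshold: float = 0.5
    origin: str = "image_origin"
    k_sd: float = 3.0
    embed_profile: str = "custom"
    run_embedding: bool = True
    run_controls: bool = True
    #: noise-control strength: per-column SD multiplier large enough to
    #: dominate the multivariate movement signal (see docs/methods.md)
    noise_control_sigma: float = 6.0
    n_states: int = 12
    ar_order: int = 3
    iters_ar: int = 20
    iters_full: int = 75
    kappa_ar: float = 1e9
    kappa_full: float = 1e8
    bootstrap_m: int = 100
    bootstrap_B: int = 1000
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _subject_trial(config: RunConfig, regime: str, subject: int):
    """Simulate and preprocess one subject's trial in one regime."""
    labels = list(range(1, config.n_configs + 1))
    seed = derive_seed(config.seed, f"simulate/{regime}/{subject}")
    library = synthgen.make_motif_library(
        labels,
        regime=regime,
        n_motifs=None if regime == "selective" else config.nonselective_motifs,
        seed=seed,
    )
    spec = synthgen.TrialSpec(
        n_configs=config.n_configs,
        on_s=config.on_s,
        off_s=config.off_s,
        fps=config.fps,
        dropout_rate=config.dropout_rate,
        noise_px=config.noise_px,
        seed=seed + 1,
        subject_id=f"{regime}_s{subject:02d}",
        mode="TIS4" if regime == "selective" else "BP2",
    )
    series, epochs, truth = synthgen.generate_trial(spec, library)
    matrix = preprocess.preprocess_series(
        series,
        epochs,
        likelihood_threshold=config.likelihood_threshold,
        origin=config.origin,
    )
    gated = preprocess.movement_gate(matrix, epochs, k_sd=config.k_sd)
    return series, gated, truth, matrix


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic study and write the summary.

    Returns the summary dict; artifacts (epoch tables, position matrices,
    syllable sequences, per-configuration selectivity tables, the group
    comparison and the summary JSON) land under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "subjects": {}, "ami": {}}
    score_frames = []

    for regime, stim_type in (("selective", "TIS"), ("nonselective", "Biphasic")):
        for subject in range(config.n_subjects):
            name = f"{regime}_s{subject:02d}"
            series, epochs, truth, matrix = _subject_trial(config, regime, subject)
            epochs.to_csv(outdir / f"{name}_epochs.csv", index=False)
            pd.DataFrame(matrix.values, columns=matrix.keypoints).to_csv(
                outdir / f"{name}_position_matrix.csv", index=False
            )

            entry: dict = {
                "n_frames": int(series.n_frames),
                "retained_configs": int(epochs["retained"].sum()),
            }

            if config.run_embedding:
                seed_e = derive_seed(config.seed, f"embed/{name}")
                emb = embedding.embed(matrix, profile=config.embed_profile, seed=seed_e)
                labels = embedding.cluster_density(
                    emb.coords, profile=config.embed_profile
                )
                tags = matrix.epoch_tag
                on = tags != "OFF"
                rep = embedding.agreement_report(
                    labels[on], tags[on], coords=emb.coords[on]
                )
                entry["ami"] = rep.ami
                entry["n_clusters"] = rep.n_clusters
                if config.run_controls:
                    for mode in ("row_shuffle", "gaussian_noise"):
                        sigma = (
                            config.noise_control_sigma
                            if mode == "gaussian_noise"
                            else 1.0
                        )
                        ctl = embedding.null_controls(
                            matrix,
                            mode,
                            seed=derive_seed(config.seed, f"{mode}/{name}"),
                            sigma_multiplier=sigma,
                        )
                        emb_c = embedding.embed(
                            ctl, profile=config.embed_profile, seed=seed_e
                        )
                        lab_c = embedding.cluster_density(
                            emb_c.coords, profile=config.embed_profile
                        )
                        try:
                            entry[f"ami_{mode}"] = embedding.ami(lab_c[on], tags[on])
                        except ValueError:
                            entry[f"ami_{mode}"] = 0.0

            model, seq = syllables.fit_syllables(
                series,
                n_states=config.n_states,
                ar_order=config.ar_order,
                iters_ar=config.iters_ar,
                iters_full=config.iters_full,
                kappa_ar=config.kappa_ar,
                kappa_full=config.kappa_full,
                seed=derive_seed(config.seed, f"arhmm/{name}"),
            )
            pd.DataFrame({"frame": np.arange(seq.n_frames), "syllable": seq.states}).to_csv(
                outdir / f"{name}_syllables.csv", index=False
            )
            entry["n_syllables"] = int(seq.n_syllables)

            table = selectivity.selectivity_table(
                seq.states, epochs, stim_type=stim_type, subject_id=name
            )
            table.to_csv(outdir / f"{name}_selectivity.csv", index=False)
            score_frames.append(table.assign(regime=regime))
            entry["mean_selectivity"] = float(table["selectivity"].mean())
            summary["subjects"][name] = entry

    scores = pd.concat(score_frames, ignore_index=True)
    scores.to_csv(outdir / "selectivity_all.csv", index=False)

    groups = {
        st: scores.loc[scores["stim_type"] == st, "selectivity"].to_numpy()
        for st in scores["stim_type"].unique()
    }
    boot = selectivity.bootstrap_means(
        groups,
        m=config.bootstrap_m,
        B=config.bootstrap_B,
        seed=derive_seed(config.seed, "bootstrap"),
    )
    summary["bootstrap"] = boot
    if len(groups) == 2:
        a, b = (groups[k] for k in ("TIS", "Biphasic"))
        summary["effects"] = selectivity.nonparametric_effects(a, b)
        try:
            reg = selectivity.beta_regression(
                scores, predictors=("stim_type",), reference={"stim_type": "Biphasic"}
            )
            summary["beta_regression"] = {
                "coef": reg["coefficients"]["coef"].to_dict(),
                "p": reg["coefficients"]["p"].to_dict(),
                "phi": reg["phi"],
            }
        except (RuntimeError, ValueError) as exc:
            summary["beta_regression"] = {"error": str(exc)}

    if config.run_embedding:
        for regime in ("selective", "nonselective"):
            vals = [
                v["ami"]
                for k, v in summary["subjects"].items()
                if k.startswith(regime) and "ami" in v
            ]
            if vals:
                summary["ami"][regime] = float(np.mean(vals))

    if config.make_figures:
        _write_figures(scores, boot, outdir)

    payload = json.dumps(_round_floats(summary), indent=2, sort_keys=True)
    (outdir / "summary.json").write_text(payload + "\n")
    return summary


def _write_figures(scores: pd.DataFrame, boot: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    order = list(scores["stim_type"].unique())
    data = [scores.loc[scores["stim_type"] == st, "selectivity"] for st in order]
    axes[0].violinplot(data, showmedians=True)
    axes[0].set_xticks(range(1, len(order) + 1), order)
    axes[0].set_ylabel("selectivity score")
    axes[0].set_title("Per-configuration selectivity")
    for st in order:
        g = boot["groups"][st]
        axes[1].errorbar(
            [st],
            [g["mean"]],
            yerr=[[g["mean"] - g["ci95"][0]], [g["ci95"][1] - g["mean"]]],
            fmt="o",
            capsize=4,
        )
    axes[1].set_title(f"Bootstrap means (m={boot['m']}, B={boot['B']})")
    fig.tight_layout()
    fig.savefig(outdir / "selectivity_summary.png", dpi=110)
    plt.close(fig)


def validate_inputs(
    pose_csv=None, sweep_log=None, expected_bodyparts=None
) -> dict:
    """Preflight validation of input files; returns a failure list, never raises."""
    failures: list[str] = []
    series = None
    if pose_csv is not None:
        path = Path(pose_csv)
        if not path.exists():
            failures.append(f"pose CSV not found: {path}")
        else:
            try:
                series = read_dlc_csv(path)
            except DLCFormatError as exc:
                failures.append(f"pose CSV malformed: {exc}")
        if series is not None and expected_bodyparts is not None:
            missing = set(expected_bodyparts) - set(series.bodyparts)
            extra = set(series.bodyparts) - set(expected_bodyparts)
            if missing or extra:
                failures.append(
                    f"keypoint schema mismatch: missing {sorted(missing)}, "
                    f"unexpected {sorted(extra)}; expected {list(expected_bodyparts)}"
                )
    if sweep_log is not None:
        path = Path(sweep_log)
        if not path.exists():
            failures.append(f"sweep log not found: {path}")
        else:
            try:
                epochs = read_sweep_log(path)
                if series is not None and len(epochs):
                    if int(epochs["off_stop"].max()) > series.n_frames:
                        failures.append(
                            "epoch spans extend beyond the recording "
                            f"({int(epochs['off_stop'].max())} > {series.n_frames})"
                        )
            except SweepLogError as exc:
                failures.append(f"sweep log invalid: {exc}")
    return {"failures": failures, "ok": not failures}
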