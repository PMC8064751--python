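"""Config-driven end-to-end orchestration on synthetic sessions.

``run_all`` reproduces the analysis flow on generated data, one subject per
sub-seed: session generation → trial assembly → band-power spectra by
condition → unit metrics and rate ratios → single-unit mutual information →
population decoding (LOOXV and count-matched curves) → group-level nested
statistics — and writes CSV/JSON artifacts plus a markdown report with
condition-contrast figures. The top-level seed fans out to per-subject and
per-stage child seeds through a fixed ``numpy.random.SeedSequence``
derivation, so any stage can be rerun in isolation reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decoding as dec
from . import group_stats as gstats
from . import information as info
from . import spectral as spec
from . import unit_metrics as um
from .session import LocomotionConfig, build_trials
from .synth import GeneratorConfig, generate_gray_block, generate_session

__all__ = ["PipelineConfig", "PipelineError", "run_all", "null_calibration"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    locomotion: LocomotionConfig = field(default_factory=LocomotionConfig)
    n_subjects: int = 2
    window_start_offset: float = 0.5
    window_length: float = 1.0
    # spectral
    freq_grid_low: float = 4.0
    freq_grid_high: float = 100.0
    freq_grid_points: int = 40
    wavelet_cycles: float = 7.0
    alpha: float = 2.5
    max_spectral_channels: int = 4   # channels per subject entering spectra
    # decoding
    decode_n_combos: int = 25
    decode_grid: tuple = ()          # empty -> automatic geometric ladder
    # stats
    n_perm: int = 2000
    make_figures: bool = True
    seed: int = 0

    def spectral_config(self) -> spec.SpectralConfig:
        return spec.SpectralConfig(
            freq_grid=np.geomspace(
                self.freq_grid_low, self.freq_grid_high, self.freq_grid_points
            ),
            alpha=self.alpha,
            wavelet_cycles=self.wavelet_cycles,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        loco = LocomotionConfig(**raw.pop("locomotion", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown pipeline config keys: {sorted(bad)}")
        if "decode_grid" in raw:
            raw["decode_grid"] = tuple(raw["decode_grid"])
        return cls(generator=gen, locomotion=loco, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["decode_grid"] = list(self.decode_grid)
        return d


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _condition_windows(sess, states_needed=("still", "running")):
    """Stimulus windows grouped by (laser, locomotion)."""
    from .session import _locomotion_state

    out = {}
    for ev in sess.grating_events():
        laser = any(
            l.onset < ev.offset and l.offset > ev.onset for l in sess.laser_events
        )
        state, _ = _locomotion_state(
            (ev.onset, ev.offset), sess.speed, LocomotionConfig()
        )
        out.setdefault((laser, state), []).append((ev.onset, ev.offset))
    return out


def _band_power_frame(sess, cfg: PipelineConfig, subject: str) -> pd.DataFrame:
    scfg = cfg.spectral_config()
    windows = _condition_windows(sess)
    rows = []
    n_ch = min(cfg.max_spectral_channels, sess.n_channels)
    for ch in range(n_ch):
        x = spec.bandpass(sess.lfp[ch], sess.lfp_rate)
        for (laser, state), wins in sorted(windows.items()):
            if len(wins) < 3:
                continue
            ps = spec.windowed_power(x, sess.lfp_rate, wins, scfg)
            adj = spec.adjust_one_over_f(ps, scfg.alpha)
            bands = {}
            for name, rng_, inc in spec.BandDefinition().items():
                try:
                    bands[name] = spec.band_power(adj, rng_, include_upper=inc)
                except ValueError:  # band outside the configured grid
                    bands[name] = np.array([np.nan])
            rows.append(
                {
                    "subject": subject,
                    "channel": ch,
                    "laser_on": laser,
                    "locomotion": state,
                    "n_windows": len(wins),
                    **{k: float(v[0]) for k, v in bands.items()},
                }
            )
    return pd.DataFrame(rows)


def _unit_metric_frame(sess, table, truth, subject: str) -> pd.DataFrame:
    feats = [
        um.waveform_features(u.mean_waveform, u.waveform_rate) for u in sess.units
    ]
    cls = um.classify_ns_bs(feats)
    rows = []
    for j, u in enumerate(sess.units):
        rates = table.counts[:, j] / table.window_length
        row = {
            "subject": subject,
            "unit_id": u.unit_id,
            "cell_class": cls.labels[j],
            "true_ns": bool(truth.is_ns[j]),
            "peak_trough_height": feats[j].peak_trough_height,
            "trough_to_peak_ms": feats[j].trough_to_peak,
            "post_trough_slope": feats[j].post_trough_slope,
            "rate_off_hz": um.condition_rate(table, j, laser=False),
            "rate_on_hz": um.condition_rate(table, j, laser=True),
            "cv_off": um.coefficient_of_variation(
                rates[table.select(laser=False)]
            ),
            "cv_on": um.coefficient_of_variation(rates[table.select(laser=True)]),
        }
        for state in ("still", "running"):
            mask = table.select(locomotion=state)
            if np.any(mask & table.laser_on) and np.any(mask & ~table.laser_on):
                row[f"laser_ratio_{state}"] = um.laser_rate_ratio(
                    table, j, locomotion=state
                )
            else:
                row[f"laser_ratio_{state}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _mi_frame(table, subject: str) -> pd.DataFrame:
    rows = []
    for j, uid in enumerate(table.unit_ids):
        row = {"subject": subject, "unit_id": uid}
        for laser in (False, True):
            res = info.mi_per_unit(table, j, laser=laser)
            row["mi_on_bits" if laser else "mi_off_bits"] = res.mi
        rows.append(row)
    return pd.DataFrame(rows)


def _decode_report(table, cfg: PipelineConfig, seed: int) -> dict:
    out = {}
    for laser in (False, True):
        mask = table.select(laser=laser)
        X = table.counts[mask]
        y = dec.group_orientations(table.stimulus_direction[mask])
        res = dec.looxv_accuracy(X, y, condition={"laser_on": laser})
        out["accuracy_on" if laser else "accuracy_off"] = res.accuracy
    grid = np.asarray(cfg.decode_grid, dtype=int) if cfg.decode_grid else None
    curve = dec.count_matched_decoding(
        table, n_combos=cfg.decode_n_combos, n_neuron_grid=grid, seed=seed
    )
    out["count_matched"] = {
        "bin_edges": curve.bin_edges.tolist(),
        "conditions": list(curve.conditions),
        "accuracy": curve.accuracy.tolist(),
        "bootstrap_se": curve.bootstrap_se.tolist(),
        "n_samples": curve.n_samples.tolist(),
        "config": curve.config,
    }
    return out


def _figures(out_dir: Path, bands_df, units_df, mi_df, decode_reports) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    made = []

    fig, axes = plt.subplots(1, 3, figsize=(10, 3), sharey=False)
    for ax, band in zip(axes, ("theta", "beta", "gamma")):
        agg = bands_df.groupby(["locomotion", "laser_on"])[band].mean()
        labels, vals = zip(*agg.items())
        ax.bar(range(len(vals)), vals, color=["k", "tab:blue"] * 2)
        ax.set_xticks(range(len(vals)))
        ax.set_xticklabels([f"{s}\nlaser={l}" for s, l in labels], fontsize=7)
        ax.set_title(band)
    axes[0].set_ylabel("power (µV²/Hz, 1/f-adj.)")
    fig.tight_layout()
    fig.savefig(fig_dir / "band_power.png", dpi=110)
    plt.close(fig)
    made.append("figures/band_power.png")

    fig, ax = plt.subplots(figsize=(4, 3))
    for cls, color in (("BS", "m"), ("NS", "c")):
        sel = units_df["cell_class"] == cls
        ax.scatter(
            units_df.loc[sel, "laser_ratio_still"],
            units_df.loc[sel, "laser_ratio_running"],
            c=color, label=cls, s=18,
        )
    ax.axhline(1, ls=":", c="gray")
    ax.axvline(1, ls=":", c="gray")
    ax.set_xlabel("laser-on/off rate ratio (still)")
    ax.set_ylabel("ratio (running)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(fig_dir / "rate_ratios.png", dpi=110)
    plt.close(fig)
    made.append("figures/rate_ratios.png")

    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.scatter(mi_df["mi_off_bits"], mi_df["mi_on_bits"], s=18)
    lim = max(mi_df[["mi_off_bits", "mi_on_bits"]].max()) * 1.1
    ax.plot([0, lim], [0, lim], "--", c="gray")
    ax.set_xlabel("MI laser-off (bits)")
    ax.set_ylabel("MI laser-on (bits)")
    fig.tight_layout()
    fig.savefig(fig_dir / "mi_scatter.png", dpi=110)
    plt.close(fig)
    made.append("figures/mi_scatter.png")

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for subject, rep in decode_reports.items():
        cm = rep["count_matched"]
        edges = np.asarray(cm["bin_edges"])
        centers = 0.5 * (edges[:-1] + edges[1:])
        for ci, (cond, color) in enumerate(zip(cm["conditions"], ("k", "tab:blue"))):
            ax.errorbar(
                centers, cm["accuracy"][ci], yerr=cm["bootstrap_se"][ci],
                color=color, alpha=0.7, label=f"{subject} {cond}",
            )
    ax.set_xlabel("population spike count")
    ax.set_ylabel("LOOXV accuracy")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(fig_dir / "count_matched.png", dpi=110)
    plt.close(fig)
    made.append("figures/count_matched.png")
    return made


def run_all(cfg: PipelineConfig, out_dir) -> dict:
    """Run the full synthetic-session analysis; returns the report dict.

    Artifacts land in ``out_dir``: per-subject trial tables, band powers,
    unit metrics, MI tables, decoding JSON, group stats JSON, report.md and
    figures. Fully reproducible for a fixed config + seed. Stage failures
    raise :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    subject_ss = ss.spawn(cfg.n_subjects)
    decode_ss = ss.spawn(cfg.n_subjects + 1)[-1]
    log_lines = [f"config_hash {_config_hash(cfg)}"]

    bands_frames, unit_frames, mi_frames = [], [], []
    decode_reports = {}
    stage = "generate"
    try:
        for si, sub_ss in enumerate(subject_ss):
            subject = f"m{si}"
            stage = f"generate[{subject}]"
            gcfg = dataclasses.replace(
                cfg.generator, seed=_child_seed(sub_ss), subject_id=subject
            )
            sess, truth = generate_session(gcfg)
            log_lines.append(f"{stage} seed {gcfg.seed}")

            stage = f"trials[{subject}]"
            table = build_trials(
                sess, cfg.window_start_offset, cfg.window_length, cfg.locomotion
            )
            table.to_csv(out / f"trials_{subject}.csv")

            stage = f"spectra[{subject}]"
            bands_frames.append(_band_power_frame(sess, cfg, subject))

            stage = f"units[{subject}]"
            unit_frames.append(_unit_metric_frame(sess, table, truth, subject))

            stage = f"mi[{subject}]"
            mi_frames.append(_mi_frame(table, subject))

            stage = f"decoding[{subject}]"
            decode_reports[subject] = _decode_report(
                table, cfg, seed=_child_seed(decode_ss.spawn(1)[0])
            )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(
            f"stage {stage} failed: {exc}; config hash {_config_hash(cfg)}"
        ) from exc

    bands_df = pd.concat(bands_frames, ignore_index=True)
    units_df = pd.concat(unit_frames, ignore_index=True)
    mi_df = pd.concat(mi_frames, ignore_index=True)
    bands_df.to_csv(out / "band_powers.csv", index=False)
    units_df.to_csv(out / "unit_metrics.csv", index=False)
    mi_df.to_csv(out / "mi.csv", index=False)
    with open(out / "decoding.json", "w") as fh:
        json.dump(decode_reports, fh, indent=1, sort_keys=True)

    stage = "stats"
    try:
        stats_report = {}
        gamma_off = bands_df[~bands_df.laser_on]
        gamma_on = bands_df[bands_df.laser_on]
        key_off = gamma_off.groupby(["subject", "channel"])["gamma"].mean()
        key_on = gamma_on.groupby(["subject", "channel"])["gamma"].mean()
        common = key_off.index.intersection(key_on.index)
        a = gstats.NestedSample(
            values=key_off.loc[common].to_numpy(),
            subject_id=np.array([s for s, _ in common]),
        )
        b = gstats.NestedSample(
            values=key_on.loc[common].to_numpy(),
            subject_id=np.array([s for s, _ in common]),
        )
        if len(set(a.subject_id)) >= 2:
            stats_report["gamma_laser_nested"] = gstats.hierarchical_permutation_test(
                a, b, n_perm=cfg.n_perm, seed=_child_seed(ss.spawn(1)[0])
            )
        stat, p = gstats.rank_tests(
            mi_df["mi_off_bits"].to_numpy(), mi_df["mi_on_bits"].to_numpy(),
            paired=True,
        )
        stats_report["mi_laser_signed_rank"] = {"statistic": stat, "p": p}
        with open(out / "stats.json", "w") as fh:
            json.dump(stats_report, fh, indent=1, sort_keys=True)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    figures = []
    if cfg.make_figures:
        stage = "figures"
        figures = _figures(out, bands_df, units_df, mi_df, decode_reports)

    report = {
        "config_hash": _config_hash(cfg),
        "n_subjects": cfg.n_subjects,
        "mean_gamma": {
            f"laser={bool(l)},{s}": float(v)
            for (s, l), v in bands_df.groupby(["locomotion", "laser_on"])["gamma"]
            .mean()
            .items()
        },
        "mean_mi_off_bits": float(mi_df["mi_off_bits"].mean()),
        "mean_mi_on_bits": float(mi_df["mi_on_bits"].mean()),
        "decoding": {
            s: {k: v for k, v in rep.items() if k != "count_matched"}
            for s, rep in decode_reports.items()
        },
        "stats": stats_report,
        "figures": figures,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)

    lines = [
        "# Synthetic-session analysis report",
        "",
        f"- config hash: `{report['config_hash']}`",
        f"- subjects: {cfg.n_subjects}",
        "",
        "## Gamma band power (1/f-adjusted, by condition)",
        "",
    ]
    lines += [f"- {k}: {v:.4g}" for k, v in report["mean_gamma"].items()]
    lines += [
        "",
        "## Single-unit mutual information (bits)",
        "",
        f"- laser-off mean: {report['mean_mi_off_bits']:.4f}",
        f"- laser-on mean: {report['mean_mi_on_bits']:.4f}",
        "",
        "## Orientation decoding (LOOXV accuracy)",
        "",
    ]
    for s, repd in report["decoding"].items():
        lines.append(
            f"- {s}: laser-off {repd['accuracy_off']:.3f}, "
            f"laser-on {repd['accuracy_on']:.3f}"
        )
    if figures:
        lines += ["", "## Figures", ""] + [f"![{f}]({f})" for f in figures]
    (out / "report.md").write_text("\n".join(lines) + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report


def null_calibration(
    n_seeds: int = 50,
    base_cfg: GeneratorConfig | None = None,
    alpha: float = 0.05,
    block_duration: float = 120.0,
    seed: int = 0,
) -> dict:
    """Fraction of seeds with a significant laser contrast under a null
    generator (no rate, pattern or gamma effects): a calibration that the
    pipeline does not manufacture optogenetic effects."""
    base = base_cfg or GeneratorConfig()
    base = dataclasses.replace(
        base,
        opto_rate_factor_bs_still=1.0, opto_rate_factor_bs_run=1.0,
        opto_rate_factor_ns_still=1.0, opto_rate_factor_ns_run=1.0,
        gamma_opto_factor=1.0, pattern_degradation=0.0,
        n_channels=4,
    )
    scfg = spec.SpectralConfig(freq_grid=np.geomspace(20.0, 100.0, 25))
    n_sig = 0
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_seeds):
        gcfg = dataclasses.replace(base, seed=_child_seed(child))
        sess, _ = generate_gray_block(gcfg, block_duration=block_duration)
        off_windows, on_windows = [], []
        for ev in sess.laser_events:
            on_windows.append((ev.onset, ev.offset))
            off_windows.append((ev.onset - ev.duration, ev.onset))
        gamma_off, gamma_on = [], []
        for ch in range(sess.n_channels):
            x = spec.bandpass(sess.lfp[ch], sess.lfp_rate)
            ps_off = spec.windowed_power(x, sess.lfp_rate, off_windows, scfg)
            ps_on = spec.windowed_power(x, sess.lfp_rate, on_windows, scfg)
            gamma_off.append(float(spec.band_power(ps_off, (30.0, 80.0))[0]))
            gamma_on.append(float(spec.band_power(ps_on, (30.0, 80.0))[0]))
        _, p = gstats.rank_tests(
            np.array(gamma_off), np.array(gamma_on), paired=True
        )
        n_sig += p < alpha
    return {
        "n_seeds": n_seeds,
        "alpha": alpha,
        "fraction_significant": n_sig / n_seeds,
    }
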