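"""End-to-end demo pipeline: generate -> decode -> cluster MCS -> connectivity.

Runs every stage of the analysis on one synthetic cohort with a single master
seed, writing a machine-readable ``stats.json``, CSV tables, and a markdown
report.  Stage seeds are fanned out from the master seed by fixed per-stage
spawn keys, so adding a stage never shifts another stage's random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster, connectivity, decode, melody_info, synth
from .layout import site_grid

log = logging.getLogger("seqrec")

_STAGE_KEYS = {
    "melodies": 0,
    "cohort": 1,
    "decode": 2,
    "cluster": 3,
    "behavior": 4,
    "connectivity": 5,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def default_effect_sites(n: int = 10) -> frozenset[int]:
    """A block of n contiguous sites over the left temporal region."""
    grid = site_grid()
    block = grid[3:7, 1:5].ravel()
    block = block[block >= 0]
    return frozenset(int(s) for s in block[:n])


#: Bilateral auditory/limbic parcels used as default connectivity hubs
#: (Rolandic operculum, insula, Heschl's gyrus, superior temporal gyrus).
DEFAULT_HUB_PARCELS: frozenset[int] = frozenset({16, 17, 28, 29, 78, 79, 80, 81})


@dataclass
class RunConfig:
    """Everything the demo pipeline needs; round-trips through YAML."""

    seed: int = 42
    n_participants: int = 20
    n_trials_per_condition: int = 40
    sfreq: float = 150.0
    noise_sd: float = 30.0
    effect_amplitude: float = 25.0
    effect_window: tuple[float, float] = (0.55, 1.18)
    n_effect_sites: int = 10
    hub_band: tuple[float, float] = (2.0, 8.0)
    shared_envelope_r: float = 0.8
    behavior_coupling: float = 0.7
    # decoding
    decode_folds: int = 8
    decode_reps: int = 10
    decode_decim: int = 8
    decode_alpha: float = 0.05
    # cluster MCS
    p_threshold: float = 0.01
    mcs_perms: int = 1000
    mcs_percentile: float = 99.9
    behavior_alpha_point: float = 0.05
    # connectivity
    sfc_trials: int = 40
    sfc_trial_len_s: float = 3.5
    k_fastest: int = 20
    degree_perms: int = 1000
    degree_alpha: float = 0.001
    make_figures: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for k in ("effect_window", "hub_band"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=list)
        return hashlib.sha1(blob.encode()).hexdigest()[:10]


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the report bundle to ``out_dir``.

    Returns the statistics dictionary that is also written to
    ``stats.json``.  Any stage failure raises with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stats: dict = {"config_hash": config.config_hash, "seed": config.seed}
    stage = "setup"
    try:
        # ---------------- melodies and information content ----------------
        stage = "melodies"
        melodies = synth.generate_melodies(
            n_per_category=config.n_trials_per_condition,
            seed=stage_seed(config.seed, "melodies"),
        )
        model = melody_info.fit_ngram(melodies, order=2, smoothing=0.5)
        mem = [m for m in melodies if m.category == "memorized"]
        nov = [m for m in melodies if m.category == "novel"]
        report = melody_info.matching_report(mem, nov, model)
        report.to_csv(out / "melody_matching.csv")
        melody_info.per_tone_table(model, melodies).to_csv(
            out / "melody_per_tone.csv", index=False)
        stats["melodies"] = {
            "n_sequences": len(melodies),
            "excerpt_duration_ms": melodies[0].duration_ms,
            "tone_rate_hz": melodies[0].tone_rate_hz,
            "mean_ic_memorized": report.loc["memorized", "mean_ic"],
            "mean_ic_novel": report.loc["novel", "mean_ic"],
            "mean_h_memorized": report.loc["memorized", "mean_h"],
            "mean_h_novel": report.loc["novel", "mean_h"],
        }

        # ---------------- cohort ----------------
        stage = "cohort"
        gt = synth.GroundTruth(
            effect_sites=default_effect_sites(config.n_effect_sites),
            effect_window=config.effect_window,
            effect_amplitude=config.effect_amplitude,
            hub_parcels=DEFAULT_HUB_PARCELS,
            hub_band=config.hub_band,
            rng_seed=config.seed,
        )
        cohort = synth.generate_cohort(
            n_participants=config.n_participants,
            ground_truth=gt,
            seed=stage_seed(config.seed, "cohort"),
            behavior_coupling=config.behavior_coupling,
            n_trials_per_condition=config.n_trials_per_condition,
            sfreq=config.sfreq,
            noise_sd=config.noise_sd,
        )
        cohort.behavior.to_csv(out / "behavior.csv", index=False)

        # ------------- per-participant passes (streamed) -------------
        stage = "decode"
        dec_seed = stage_seed(config.seed, "decode")
        acc_stack, times_dec = [], None
        grad_means = {"memorized": [], "novel": []}
        mag_means = {"memorized": [], "novel": []}
        times_full = None
        for i in range(config.n_participants):
            ep = cohort.epochs(i)
            res = decode.decode_time_series(
                ep, n_folds=config.decode_folds,
                n_repetitions=config.decode_reps,
                seed=dec_seed + i, decim=config.decode_decim,
                correct_only=True,
            )
            acc_stack.append(res.accuracy)
            times_dec = res.times
            means = cluster.average_trials(ep, correct_only=True)
            for cond in ("memorized", "novel"):
                grad_means[cond].append(
                    cluster.combine_planar(means[cond], ep.channels))
                mag_idx = [k for k, ch in enumerate(ep.channels)
                           if ch.kind == "magnetometer"]
                mag_means[cond].append(means[cond][mag_idx])
            times_full = ep.times
        acc_stack = np.stack(acc_stack)
        sp = decode.signperm_fdr(
            acc_stack, chance=0.5, alpha=config.decode_alpha,
            seed=dec_seed, n_perms=1000,
        )
        pd.DataFrame({
            "time": times_dec,
            "accuracy": acc_stack.mean(axis=0),
            "q": sp.qvalues,
            "significant": sp.mask,
        }).to_csv(out / "decoding.csv", index=False)
        stats["decoding"] = {
            "mean_accuracy": float(acc_stack.mean()),
            "max_accuracy": float(acc_stack.mean(axis=0).max()),
            "n_significant_timepoints": int(sp.mask.sum()),
        }

        # ---------------- sensor cluster MCS ----------------
        stage = "cluster"
        mcs_seed = stage_seed(config.seed, "cluster")
        grad_a = np.stack(grad_means["memorized"])
        grad_b = np.stack(grad_means["novel"])
        outcome = cluster.sensor_mcs(
            grad_a, grad_b, times_full,
            p_threshold=config.p_threshold, n_perms=config.mcs_perms,
            percentile=config.mcs_percentile, seed=mcs_seed,
        )
        grid = site_grid()
        tables = []
        for sign, res in (("positive", outcome.positive),
                          ("negative", outcome.negative)):
            if res is not None:
                tab = cluster.cluster_table(res, grid)
                tab.insert(0, "sensor", "grad")
                tables.append(tab)
        window = outcome.significant_window()
        mag_outcome = cluster.magnetometer_followup(
            np.stack(mag_means["memorized"]), np.stack(mag_means["novel"]),
            times_full, window,
            p_threshold=config.p_threshold, n_perms=config.mcs_perms,
            percentile=config.mcs_percentile, seed=mcs_seed + 7,
        )
        if mag_outcome.ran:
            for res in (mag_outcome.positive, mag_outcome.negative):
                tab = cluster.cluster_table(res, grid)
                tab.insert(0, "sensor", "mag")
                tables.append(tab)
        all_clusters = pd.concat(tables, ignore_index=True) if tables \
            else pd.DataFrame()
        all_clusters.to_csv(out / "clusters.csv", index=False)
        n_sig = int(all_clusters["significant"].sum()) if len(all_clusters) \
            else 0
        stats["cluster_mcs"] = {
            "n_clusters": int(len(all_clusters)),
            "n_significant": n_sig,
            "significant_window_s": list(window) if window else None,
            "magnetometer_followup_ran": mag_outcome.ran,
        }

        # ---------------- behavior scans ----------------
        stage = "behavior"
        beh_seed = stage_seed(config.seed, "behavior")
        beh_stats = {}
        if window is not None:
            sig_sites = sorted({
                int(grid[r, c])
                for res in (outcome.positive, outcome.negative) if res
                for cl in res.significant for (r, c, _) in cl.cells
            })
            diff = grad_a[:, sig_sites, :].mean(axis=1) - \
                grad_b[:, sig_sites, :].mean(axis=1)
            for k, col in enumerate(["wm", "liking", "familiarity", "msi"]):
                scan = cluster.behavior_scan(
                    diff, cohort.behavior[col].to_numpy(),
                    alpha_point=config.behavior_alpha_point,
                    n_perms=config.mcs_perms, seed=beh_seed + k, measure=col,
                )
                beh_stats[col] = {
                    "n_significant_clusters":
                        int(scan.clusters["significant"].sum())
                        if len(scan.clusters) else 0,
                }
            scan = cluster.behavior_scan(
                diff, None, groups=cohort.behavior["group"].to_numpy(),
                alpha_point=config.behavior_alpha_point,
                n_perms=config.mcs_perms, seed=beh_seed + 10,
                measure="expertise_anova",
            )
            beh_stats["expertise_anova"] = {
                "n_significant_clusters":
                    int(scan.clusters["significant"].sum())
                    if len(scan.clusters) else 0,
            }
        stats["behavior"] = beh_stats

        # ---------------- connectivity ----------------
        stage = "connectivity"
        con_seed = stage_seed(config.seed, "connectivity")
        bands = connectivity.DEFAULT_BANDS
        stacks = {b.name: {"task": [], "baseline": []} for b in bands}
        for i in range(config.n_participants):
            task, base = synth.generate_parcels(
                n_trials=config.sfc_trials, sfreq=config.sfreq,
                ground_truth=gt, shared_envelope_r=config.shared_envelope_r,
                seed=con_seed + i, trial_len_s=config.sfc_trial_len_s,
            )
            mats = connectivity.participant_sfc(
                task, base, bands, k_fastest=config.k_fastest)
            for b in bands:
                for role in ("task", "baseline"):
                    stacks[b.name][role].append(mats[b.name][role])
        gm = pd.DataFrame({
            b.name: [m.mean() for m in stacks[b.name]["task"]] for b in bands
        })
        anova = connectivity.band_anova(gm)
        gm.to_csv(out / "sfc_global_means.csv", index=False)
        anova.tukey.to_csv(out / "sfc_tukey.csv", index=False)
        degree_stats = {}
        degree_tables = []
        for bi, b in enumerate(bands):
            B = connectivity.edge_wilcoxon(
                np.stack(stacks[b.name]["task"]),
                np.stack(stacks[b.name]["baseline"]),
            )
            # node-wise null: the pooled maximum-based threshold scales with
            # the saturated signed-rank z and cannot flag hubs at demo scale
            dres = connectivity.degree_mcs(
                B, n_perms=config.degree_perms, alpha=config.degree_alpha,
                n_bands=len(bands), seed=con_seed + 100 + bi,
                pool="nodewise",
            )
            tab = connectivity.degree_table(dres, synth.AAL90_LABELS)
            tab.insert(0, "band", b.name)
            degree_tables.append(tab)
            degree_stats[b.name] = {
                "n_significant": int(dres.significant.sum()),
                "significant_parcels": [
                    synth.AAL90_LABELS[i]
                    for i in np.flatnonzero(dres.significant)
                ],
            }
        pd.concat(degree_tables, ignore_index=True).to_csv(
            out / "degree.csv", index=False)
        stats["connectivity"] = {
            "anova_f": anova.f,
            "anova_df": [anova.df_between, anova.df_within],
            "anova_p": anova.pvalue,
            "alpha_per_band": config.degree_alpha / len(bands),
            "degree": degree_stats,
        }

        # ---------------- report ----------------
        stage = "report"
        if config.make_figures:
            _figures(out, times_dec, acc_stack, sp, gm)
        (out / "stats.json").write_text(
            json.dumps(_jsonable(stats), indent=1))
        _markdown_report(out, config, stats, all_clusters)
        config.to_yaml(out / f"config_{config.config_hash}.yaml")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (config {config.config_hash}, "
            f"seed {config.seed})"
        ) from exc
    return stats


def _figures(out: Path, times, acc_stack, sp, gm) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.2))
    mean_acc = acc_stack.mean(axis=0)
    ax.plot(times, mean_acc, lw=1.5)
    ax.axhline(0.5, color="gray", ls="--", lw=0.8)
    if sp.mask.any():
        ax.plot(times[sp.mask], np.full(sp.mask.sum(), 0.45), ".",
                color="crimson", ms=3)
    ax.set(xlabel="time (s)", ylabel="accuracy",
           title="Time-resolved decoding (red: FDR-significant)")
    fig.tight_layout()
    fig.savefig(out / "decoding.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.violinplot([gm[c] for c in gm.columns], showmeans=True)
    ax.set_xticks(range(1, len(gm.columns) + 1), list(gm.columns))
    ax.set(ylabel="global SFC", title="Global connectivity per band")
    fig.tight_layout()
    fig.savefig(out / "sfc_bands.png", dpi=120)
    plt.close(fig)


def _markdown_report(out: Path, config: RunConfig, stats: dict,
                     clusters: pd.DataFrame) -> None:
    lines = [
        "# Sequence-recognition pipeline report",
        f"config `{config.config_hash}`, seed {config.seed}",
        "",
        "## Decoding",
        f"- mean accuracy {stats['decoding']['mean_accuracy']:.3f} "
        f"(chance 0.5), peak {stats['decoding']['max_accuracy']:.3f}",
        f"- FDR-significant timepoints: "
        f"{stats['decoding']['n_significant_timepoints']}",
        "",
        "## Sensor cluster MCS",
        f"- {stats['cluster_mcs']['n_significant']} significant cluster(s) "
        f"of {stats['cluster_mcs']['n_clusters']}",
    ]
    if stats["cluster_mcs"]["significant_window_s"]:
        w = stats["cluster_mcs"]["significant_window_s"]
        lines.append(f"- significant window {w[0]:.3f}-{w[1]:.3f} s")
    else:
        lines.append("- no significant clusters")
    lines += [
        "",
        "## Connectivity",
        f"- band ANOVA F({stats['connectivity']['anova_df'][0]},"
        f"{stats['connectivity']['anova_df'][1]}) = "
        f"{stats['connectivity']['anova_f']:.2f}, "
        f"p = {stats['connectivity']['anova_p']:.2e}",
        f"- per-band alpha {stats['connectivity']['alpha_per_band']:.1e}",
    ]
    for band, d in stats["connectivity"]["degree"].items():
        lines.append(
            f"- {band}: {d['n_significant']} significant parcel(s)")
    (out / "report.md").write_text("\n".join(lines) + "\n")
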