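"""Orchestration: run every analysis stage on one dataset, reproducibly.

Stages run in dependency order (simulate -> preprocess -> tuning ->
discriminability -> choice -> correlations -> information), each emitting
its delimited table(s) into the output directory as it completes, followed
by a JSON summary of the headline early-vs-late comparisons and a
provenance block (config hash, seed, library versions).  All randomness
flows from the single config seed through named substreams, so identical
configs give byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from . import choice as choice_mod
from . import correlations as corr_mod
from . import discriminability as disc_mod
from . import information as info_mod
from . import preprocess as prep_mod
from . import tuning as tuning_mod
from .synthetic_data import (GeneratorConfig, HARD_CONTRASTS,
                             generate_dataset, simulate_binned_sessions,
                             write_sessions, config_from_yaml,
                             config_to_yaml)

__all__ = ["RunConfig", "PipelineError", "run"]

STAGES = ("simulate", "preprocess", "tuning", "discriminability", "choice",
          "correlations", "information")

#: Mirrored hard test-test pairs (low, high) used for learning comparisons.
HARD_PAIRS = ((27.0, 33.0), (28.0, 32.0), (29.0, 31.0))


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    outdir: str = "run_out"
    early_days: tuple | None = None      # default: first 5 days
    late_days: tuple | None = None       # default: last 5 days
    n_period_days: int = 5
    stages: tuple = STAGES
    alpha: float = 0.05

    def __post_init__(self):
        days = range(1, self.generator.n_days + 1)
        if self.early_days is None:
            self.early_days = tuple(days)[:self.n_period_days]
        if self.late_days is None:
            self.late_days = tuple(days)[-self.n_period_days:]
        if set(self.early_days) & set(self.late_days):
            raise ValueError("early and late day windows must not overlap")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        gen = d.pop("generator", None)
        cfg = GeneratorConfig() if gen is None else _generator_from_dict(gen)
        for key in ("early_days", "late_days", "stages"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(generator=cfg, **d)


def _generator_from_dict(d) -> GeneratorConfig:
    import tempfile
    with tempfile.NamedTemporaryFile("w", suffix=".yaml",
                                     delete=False) as fh:
        yaml.safe_dump(d, fh)
        path = fh.name
    return config_from_yaml(path)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True,
                      default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _channel_day_rates(session, channel, levels):
    """(rates, trial counts) per contrast from the test epoch (spikes/s)."""
    win_s = prep_mod.session_window_seconds(session)
    test = session.epoch("test")[:, channel].astype(float)
    rates, counts = [], []
    for c in levels:
        sel = session.test_contrast == c
        rates.append(float(np.mean(test[sel])) / win_s)
        counts.append(int(np.sum(sel)))
    return np.array(rates), np.array(counts)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config, out):
    sessions = generate_dataset(config.generator)
    write_sessions(sessions, out / "sessions")
    rows = []
    for s in sessions:
        for c in np.unique(s.test_contrast):
            sel = s.test_contrast == c
            rows.append({"day": s.day, "contrast": c,
                         "n_trials": int(sel.sum()),
                         "fraction_correct": float(s.correct[sel].mean())})
    pd.DataFrame(rows).to_csv(out / "behaviour.csv", index=False)
    return sessions


def _stage_preprocess(config, out, sessions):
    records = [prep_mod.compute_snr(s, ch)
               for s in sessions for ch in range(s.n_channels)]
    report = prep_mod.inclusion_report(records)
    report.to_csv(out / "inclusion.csv", index=False)
    included = prep_mod.select_channels(records)
    if not included:
        raise ValueError("no channels pass the SNR inclusion rule")

    binned = simulate_binned_sessions(config.generator, n_sessions=3,
                                      n_trials=120)
    window, _scores = prep_mod.find_analysis_window(
        binned, starts=np.arange(0.0, 257.0, 16.0))
    with open(out / "window.json", "w") as fh:
        json.dump({"start_ms": window.start_ms,
                   "length_ms": window.length_ms}, fh, indent=1,
                  sort_keys=True)
    return included, window


def _stage_tuning(config, out, sessions, included):
    levels = np.asarray(config.generator.contrast_levels, dtype=float)
    fits = {}
    rows = []
    for ch in included:
        by_day = []
        for s in sessions:
            rates, counts = _channel_day_rates(s, ch, levels)
            p = tuning_mod.fit_naka_rushton(levels, rates, weights=counts)
            by_day.append(p)
        reversed_ch = tuning_mod.classify_reversed(by_day)
        fits[ch] = (by_day, reversed_ch)
        for s, p in zip(sessions, by_day):
            rows.append({"channel": ch, "day": s.day, "rmax": p.rmax,
                         "c50": p.c50, "n": p.n, "m": p.m,
                         "slope30": p.slope30,
                         "reversed": reversed_ch, "rss": p.rss})
    crf = pd.DataFrame(rows)
    crf.to_csv(out / "crf.csv", index=False)

    days = sorted(crf["day"].unique())
    slope_by_day = [
        np.mean([tuning_mod.rectified_slope30(fits[ch][0][d - 1],
                                              fits[ch][1])
                 for ch in included])
        for d in days]
    dist_by_day = [
        np.mean([tuning_mod.distance_to_boundary(fits[ch][0][d - 1].c50)
                 for ch in included if not fits[ch][0][d - 1].flat])
        for d in days]
    trends = {
        "slope30": tuning_mod.trend_test(slope_by_day),
        "c50_distance": tuning_mod.trend_test(dist_by_day),
    }
    return fits, trends


def _stage_discriminability(config, out, sessions, included, fits):
    levels = np.asarray(config.generator.contrast_levels, dtype=float)
    disc_rows, neuro_rows = [], []
    pne_dist_by_day = {s.day: [] for s in sessions}
    hard_diff_rows = []
    for ch in included:
        reversed_ch = fits[ch][1]
        for s in sessions:
            sample = s.epoch("sample")[:, ch]
            test = s.epoch("test")[:, ch]
            aurocs = []
            for c in levels:
                sel = s.test_contrast == c
                a = disc_mod.auroc(sample[sel], test[sel])
                cb = disc_mod.cobe(sample[sel], test[sel])
                if reversed_ch:
                    a, cb = 1.0 - a, 1.0 - cb
                aurocs.append(a)
                disc_rows.append({"channel": ch, "day": s.day,
                                  "contrast": c, "auroc": a, "cobe": cb,
                                  "n_trials": int(sel.sum()),
                                  "subset": "all"})
            params = disc_mod.fit_neurometric(levels, np.array(aurocs))
            pne = disc_mod.compute_pne(params)
            neuro_rows.append({"channel": ch, "day": s.day,
                               "alpha": params.alpha, "beta": params.beta,
                               "gamma": params.gamma, "delta": params.delta,
                               "slope30": params.slope30,
                               "pne": np.nan if pne is None else pne,
                               "flagged": params.flagged})
            if pne is not None:
                pne_dist_by_day[s.day].append(
                    tuning_mod.distance_to_boundary(pne))
            by_c = {c: a for c, a in zip(levels, aurocs)}
            hard_diff_rows.append({
                "channel": ch, "day": s.day,
                "value": np.mean([by_c[hi] - by_c[lo]
                                  for lo, hi in HARD_PAIRS])})

    pd.DataFrame(disc_rows).to_csv(out / "discriminability.csv", index=False)
    pd.DataFrame(neuro_rows).to_csv(out / "neurometric.csv", index=False)

    pne_days = [d for d in sorted(pne_dist_by_day) if pne_dist_by_day[d]]
    pne_trend = tuning_mod.trend_test(
        [np.mean(pne_dist_by_day[d]) for d in pne_days],
        days=pne_days)

    hard_diff = pd.DataFrame(hard_diff_rows)
    early_late = disc_mod.early_late_difference(
        hard_diff, config.early_days, config.late_days)

    # test-test AUROC on correct / error trials, pooled per period
    tt_rows = []
    for subset in ("correct", "error"):
        for ch in included:
            reversed_ch = fits[ch][1]
            for period, days in (("early", config.early_days),
                                 ("late", config.late_days)):
                vals = []
                for lo, hi in HARD_PAIRS:
                    x_lo, x_hi = [], []
                    for s in sessions:
                        if s.day not in days:
                            continue
                        keep = s.correct if subset == "correct" \
                            else ~s.correct
                        x_lo.append(s.epoch("test")[
                            keep & (s.test_contrast == lo), ch])
                        x_hi.append(s.epoch("test")[
                            keep & (s.test_contrast == hi), ch])
                    x_lo = np.concatenate(x_lo)
                    x_hi = np.concatenate(x_hi)
                    if x_lo.size == 0 or x_hi.size == 0:
                        continue   # skipped cell (e.g. no error trials)
                    vals.append(disc_mod.test_test_auroc(
                        x_lo, x_hi, reversed_channel=reversed_ch))
                if vals:
                    tt_rows.append({"channel": ch, "period": period,
                                    "subset": subset,
                                    "auroc": float(np.mean(vals))})
    tt = pd.DataFrame(tt_rows)
    tt.to_csv(out / "test_test.csv", index=False)

    tt_tests = {}
    for subset in ("correct", "error"):
        sub = tt[tt["subset"] == subset]
        piv = sub.pivot(index="channel", columns="period", values="auroc")
        piv = piv.dropna()
        if len(piv) >= 5:
            diffs = (piv["late"] - piv["early"]).to_numpy()
            if np.allclose(diffs, 0.0):
                stat, p = float("nan"), 1.0
            else:
                from scipy import stats as sps
                stat, p = sps.wilcoxon(diffs, alternative="two-sided")
            tt_tests[subset] = {"mean_early": float(piv["early"].mean()),
                                "mean_late": float(piv["late"].mean()),
                                "p": float(p), "n": int(len(piv))}
    return {
        "pne_trend": pne_trend,
        "hard_diff_early_late": early_late,
        "test_test": tt_tests,
    }


def _stage_choice(config, out, sessions, included, fits):
    rows = []
    for ch in included:
        reversed_ch = fits[ch][1]
        for s in sessions:
            choices = choice_mod.normalize_choices(s.choice)
            for c in HARD_CONTRASTS:
                sel = s.test_contrast == c
                cp = choice_mod.choice_probability(
                    s.epoch("test")[sel, ch], choices[sel], reversed_ch)
                cpd = choice_mod.diff_choice_probability(
                    s.epoch("test")[sel, ch], s.epoch("sample")[sel, ch],
                    choices[sel], reversed_ch)
                rows.append({"channel": ch, "day": s.day, "contrast": c,
                             "cp": np.nan if cp is None else cp,
                             "cp_diff": np.nan if cpd is None else cpd,
                             "n_lower": int(np.sum(~choices[sel])),
                             "n_higher": int(np.sum(choices[sel]))})
    cp_table = pd.DataFrame(rows)
    cp_table.to_csv(out / "cp.csv", index=False)

    defined = cp_table.dropna(subset=["cp"])
    pooled = choice_mod.pool_cp_early_late(defined, config.early_days,
                                           config.late_days)
    pooled.long_table.to_csv(out / "cp_period_table.csv", index=False)
    defined_diff = cp_table.dropna(subset=["cp_diff"]).drop(
        columns="cp").rename(columns={"cp_diff": "cp"})[
        ["channel", "day", "contrast", "cp"]]
    pooled_diff = choice_mod.pool_cp_early_late(
        defined_diff, config.early_days, config.late_days)
    return {"cp": pooled, "cp_diff": pooled_diff}


def _period_sessions(sessions, days):
    return [s for s in sessions if s.day in days]


def _stage_correlations(config, out, sessions, included, fits,
                        single_info_by_period):
    levels = np.asarray(config.generator.contrast_levels, dtype=float)
    ch_idx = {ch: i for i, ch in enumerate(included)}
    n_inc = len(included)
    iu = np.triu_indices(n_inc, k=1)

    pair_rows = []
    slope_cells = {}
    per_period = {}
    for period, days in (("early", config.early_days),
                         ("late", config.late_days)):
        period_sessions = _period_sessions(sessions, days)
        # noise correlations: z per (pair, contrast, day), averaged in z
        z_sum = np.zeros(iu[0].size)
        z_n = np.zeros(iu[0].size)
        for s in period_sessions:
            counts = s.epoch("test")[:, included]
            for c in levels:
                sel = s.test_contrast == c
                r = corr_mod.pairwise_noise_correlations(counts[sel])
                z = corr_mod.fisher_z(r)
                ok = np.isfinite(z)
                z_sum[ok] += z[ok]
                z_n[ok] += 1
        noise_z = np.where(z_n > 0, z_sum / np.maximum(z_n, 1), np.nan)
        noise_r = corr_mod.inverse_fisher_z(noise_z)

        # signal correlations from period-mean tuning curves
        tuning = np.stack([
            np.mean([_channel_day_rates(s, ch, levels)[0]
                     for s in period_sessions], axis=0)
            for ch in included], axis=0)
        with np.errstate(invalid="ignore"):
            sig = np.corrcoef(tuning)
        signal_r = sig[iu]
        signal_z = corr_mod.fisher_z(signal_r)

        tercile = corr_mod.assign_info_terciles(
            single_info_by_period[period])
        pair_terc = []
        for a, b in zip(*iu):
            ta, tb = tercile[included[a]], tercile[included[b]]
            pair_terc.append(ta if ta == tb else "mixed")
        pair_terc = np.array(pair_terc)

        for k, (a, b) in enumerate(zip(*iu)):
            pair_rows.append({"i": included[a], "j": included[b],
                              "period": period, "contrast": "pooled",
                              "noise_r": noise_r[k], "noise_z": noise_z[k],
                              "signal_r": signal_r[k],
                              "info_tercile": pair_terc[k]})

        per_period[period] = {"signal_z": signal_z, "noise_z": noise_z,
                              "tercile": pair_terc,
                              "mean_noise_r": float(np.nanmean(noise_r))}
        for terc in ("bottom", "top"):
            for sign, sel_sign in (("positive", signal_r > 0),
                                   ("negative", signal_r < 0)):
                sel = sel_sign & (pair_terc == terc) & np.isfinite(noise_z)
                slope = corr_mod.signal_noise_slope(signal_z[sel],
                                                    noise_z[sel])
                slope_cells[f"{period}/{sign}/{terc}"] = {
                    "slope": slope, "n_pairs": int(sel.sum())}

    pd.DataFrame(pair_rows).to_csv(out / "pairs.csv", index=False)

    # permutation test per positive-signal cell, early vs late
    perm_results = {}
    rng = np.random.default_rng([config.generator.seed, 41])
    for terc in ("bottom", "top"):
        sels = {}
        for period in ("early", "late"):
            d = per_period[period]
            sels[period] = ((d["signal_z"] > 0) & (d["tercile"] == terc)
                            & np.isfinite(d["noise_z"]))
        if sels["early"].sum() < 10 or sels["late"].sum() < 10:
            continue
        res = corr_mod.slope_permutation_test(
            per_period["early"]["signal_z"][sels["early"]],
            per_period["early"]["noise_z"][sels["early"]],
            per_period["late"]["signal_z"][sels["late"]],
            per_period["late"]["noise_z"][sels["late"]],
            rng=rng)
        perm_results[f"positive/{terc}"] = res

    with open(out / "slopes.json", "w") as fh:
        json.dump({
            "cells": slope_cells,
            "permutation": {k: dataclasses.asdict(v)
                            for k, v in perm_results.items()},
        }, fh, indent=1, sort_keys=True)
    return per_period, slope_cells, perm_results


def _equalized_for_pair(sessions, days, included, pair):
    per_day = []
    for s in sessions:
        if s.day not in days:
            continue
        keep = s.correct
        low = s.epoch("test")[keep & (s.test_contrast == pair.c_low)][:,
                                                                     included]
        high = s.epoch("test")[keep & (s.test_contrast == pair.c_high)][:,
                                                                       included]
        per_day.append((low, high))
    return info_mod.equalize_trials(per_day)


def _stage_information(config, out, sessions, included, pairs=None):
    pairs = info_mod.DEFAULT_PAIRS if pairs is None else pairs
    single_rows, pop_rows = [], []
    expfits = {}
    single_by_period = {"early": {}, "late": {}}
    rng = np.random.default_rng([config.generator.seed, 42])
    for pair in pairs:
        for period, days in (("early", config.early_days),
                             ("late", config.late_days)):
            low, high = _equalized_for_pair(sessions, days, included, pair)
            n = low.shape[0]
            infos = info_mod.single_channel_infos(low, high, pair.delta_s)
            for ch, v in zip(included, infos):
                single_rows.append({"channel": ch,
                                    "pair": f"{pair.c_low:g}-{pair.c_high:g}",
                                    "period": period, "info": v,
                                    "n_trials": n})
            order = sorted(range(len(included)),
                           key=lambda j: (-infos[j], included[j]))
            for shuffled in (False, True):
                curve = info_mod.population_info_curve(
                    low, high, pair.delta_s, order=order,
                    shuffled=shuffled, rng=rng)
                for _, row in curve.iterrows():
                    pop_rows.append({
                        "pair": f"{pair.c_low:g}-{pair.c_high:g}",
                        "period": period, "shuffled": shuffled,
                        "size": int(row["size"]), "info": row["info"],
                        "n_trials": n})
            fit = info_mod.fit_exponential_rank(infos)
            expfits[f"{pair.c_low:g}-{pair.c_high:g}/{period}"] = {
                "c": fit.c, "b": fit.b, "lam": fit.lam, "vaf": fit.vaf}
            for ch, v in zip(included, infos):
                single_by_period[period].setdefault(ch, []).append(v)

    single = pd.DataFrame(single_rows)
    single.to_csv(out / "info_single.csv", index=False)
    pop = pd.DataFrame(pop_rows)
    pop.to_csv(out / "info_population.csv", index=False)
    with open(out / "expfit.json", "w") as fh:
        json.dump(expfits, fh, indent=1, sort_keys=True)

    gain_rows = []
    for pair in pairs:
        key = f"{pair.c_low:g}-{pair.c_high:g}"
        sub = single[single["pair"] == key].pivot(
            index="channel", columns="period", values="info")
        try:
            res = info_mod.proportional_gain(sub["early"].to_numpy(),
                                             sub["late"].to_numpy(),
                                             channels=sub.index.to_numpy())
            gain_rows.append({"pair": key, "rho": res.rho, "p": res.p,
                              "n": len(res.gains)})
        except ValueError:
            gain_rows.append({"pair": key, "rho": np.nan, "p": np.nan,
                              "n": 0})
    pd.DataFrame(gain_rows).to_csv(out / "proportional_gain.csv",
                                   index=False)

    info_mean_by_period = {
        period: {ch: float(np.mean(v)) for ch, v in d.items()}
        for period, d in single_by_period.items()}
    return single, pop, expfits, info_mean_by_period


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    return x


def run(config: RunConfig) -> dict:
    """Execute the configured stages and return the summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config_to_yaml(config.generator, out / "generator.yaml")
    alpha = config.alpha

    state = {}
    stage = "simulate"
    try:
        sessions = _stage_simulate(config, out)
        stage = "preprocess"
        included, window = _stage_preprocess(config, out, sessions)
        stage = "tuning"
        fits, trends = _stage_tuning(config, out, sessions, included)
        stage = "discriminability"
        disc = _stage_discriminability(config, out, sessions, included, fits)
        stage = "choice"
        cps = _stage_choice(config, out, sessions, included, fits)
        stage = "information"
        single, pop, expfits, info_by_period = _stage_information(
            config, out, sessions, included)
        stage = "correlations"
        per_period, slope_cells, perm = _stage_correlations(
            config, out, sessions, included, fits, info_by_period)
    except Exception as exc:   # noqa: BLE001 - named-stage contract
        raise PipelineError(stage, exc) from exc

    hardest = "29-31"
    pop_full = pop[(pop["size"] == len(included)) & (~pop["shuffled"])]
    info_early = float(pop_full[(pop_full["period"] == "early")
                                & (pop_full["pair"] == hardest)]["info"].iloc[0])
    info_late = float(pop_full[(pop_full["period"] == "late")
                               & (pop_full["pair"] == hardest)]["info"].iloc[0])

    cp_tab = cps["cp"].per_contrast
    summary = {
        "included_channels": list(map(int, included)),
        "window": {"start_ms": window.start_ms,
                   "length_ms": window.length_ms},
        "trends": {
            "slope30": {"rho": _round(trends["slope30"].rho),
                        "p": _round(trends["slope30"].p)},
            "c50_distance": {"rho": _round(trends["c50_distance"].rho),
                             "p": _round(trends["c50_distance"].p)},
            "pne_distance": {"rho": _round(disc["pne_trend"].rho),
                             "p": _round(disc["pne_trend"].p)},
        },
        "hard_auroc_difference": {
            "mean_early": _round(float(
                disc["hard_diff_early_late"].per_channel["early"].mean())),
            "mean_late": _round(float(
                disc["hard_diff_early_late"].per_channel["late"].mean())),
            "p": _round(disc["hard_diff_early_late"].p),
        },
        "test_test": {k: {kk: _round(vv) for kk, vv in v.items()}
                      for k, v in disc["test_test"].items()},
        "cp": {
            "per_contrast": [
                {"contrast": _round(float(r["contrast"])),
                 "mean_early": _round(float(r["mean_early"])),
                 "mean_late": _round(float(r["mean_late"])),
                 "p": _round(float(r["p"]))}
                for _, r in cp_tab.iterrows()],
        },
        "noise_correlation": {
            "mean_early": _round(per_period["early"]["mean_noise_r"]),
            "mean_late": _round(per_period["late"]["mean_noise_r"]),
        },
        "information": {
            "pair": hardest,
            "population_early": _round(info_early),
            "population_late": _round(info_late),
        },
        "slope_permutation": {
            k: {"slope_early": _round(v.slope_early),
                "slope_late": _round(v.slope_late),
                "lo": _round(v.lo), "hi": _round(v.hi),
                "significant": v.significant}
            for k, v in perm.items()},
        "flags": {},
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.generator.seed,
            "package_version": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }

    cp_shift_frac = (float(np.mean(cp_tab["p"] < alpha))
                     if len(cp_tab) else 0.0)
    summary["flags"] = {
        "slope30_steepened": bool(trends["slope30"].rho > 0
                                  and trends["slope30"].p < alpha),
        "c50_distance_decreased": bool(trends["c50_distance"].rho < 0
                                       and trends["c50_distance"].p < alpha),
        "pne_distance_decreased": bool(disc["pne_trend"].rho < 0
                                       and disc["pne_trend"].p < alpha),
        "hard_auroc_diff_increased": bool(
            disc["hard_diff_early_late"].p < alpha
            and disc["hard_diff_early_late"].per_channel["diff"].mean() > 0),
        "cp_shifted": bool(cp_shift_frac >= 0.5),
        "noise_correlation_decreased": bool(
            per_period["late"]["mean_noise_r"]
            < per_period["early"]["mean_noise_r"]),
        "population_info_increased": bool(info_late > info_early),
    }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
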