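"""Run the full dual-track analysis over a collection of stock series.

For every series, all three growth models are fitted twice: by posterior
sampling + bridge-sampling evidence (the Bayesian track) and by maximum
likelihood + Akaike weights (the likelihood track).  The per-series results
are assembled into a :class:`SelectionSummary`, from which the headline
aggregates are computed: which model wins how often under each track, how
often the winner has overwhelming (> 95%) support, and which model
recommends the most conservative optimal escapement on each of two scales
(fraction of fitted carrying capacity, fraction of maximum observed
biomass), including how often the Hockey-Stick target exceeds the B60
reference point of 0.6 k.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes, likelihood
from .bayes import BridgeConfig, McmcConfig
from .data_io import StockSeries
from .escapement import escapement_fraction
from .models import Model

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "SelectionSummary",
    "run_study",
    "conservativeness_report",
    "render_figures",
]

MODELS = tuple(Model)


@dataclass(frozen=True)
class StudyConfig:
    """Settings for a full study run.

    ``support_threshold`` (default 0.95) defines "overwhelming" support;
    ``b60_fraction`` (default 0.6) is the biomass reference point the
    Hockey-Stick escapement is compared against.  ``cache_dir``, when set,
    stores one JSON per finished series so an interrupted study resumes.
    """

    mcmc: McmcConfig = field(default_factory=McmcConfig)
    bridge: BridgeConfig = field(default_factory=BridgeConfig)
    n_starts: int = 8
    support_threshold: float = 0.95
    b60_fraction: float = 0.6
    seed: int = 0
    cache_dir: Path | None = None
    tie_tol: float = 1e-12


def _series_seed(config_seed: int, sid: str) -> int:
    return (config_seed * 1_000_003 + zlib.crc32(sid.encode())) % (2 ** 31)


def analyze_series(series: StockSeries, config: StudyConfig) -> dict:
    """Fit all three models to one series under both tracks.

    Returns a flat record with per-model Bayesian model probabilities,
    Akaike weights, and median optimal escapement on both scales under
    both tracks.  The MLE search starts from the highest-posterior draw of
    the corresponding Markov chain (plus Latin-hypercube restarts).
    """
    base_seed = _series_seed(config.seed, series.id)
    row: dict = {"id": series.id, "T": series.T,
                 "max_biomass": series.max_biomass, "flagged_chains": 0}

    draws_by_model: dict[Model, bayes.PosteriorDraws] = {}
    evidences: dict[Model, bayes.ModelEvidence] = {}
    mle_fits: dict[Model, likelihood.MleFit] = {}
    for j, model in enumerate(MODELS):
        mcmc = replace(config.mcmc, seed=(base_seed + j) % (2 ** 31))
        draws = bayes.sample_posterior(model, series, mcmc)
        if draws.flagged:
            row["flagged_chains"] += 1
        draws_by_model[model] = draws
        bridge = replace(config.bridge, seed=(base_seed + 100 + j) % (2 ** 31))
        evidences[model] = bayes.log_marginal_likelihood(
            model, series, draws, bridge, force=True)

        best_idx = np.unravel_index(np.argmax(draws.log_post),
                                    draws.log_post.shape)
        init = tuple(draws.draws[best_idx])
        mle_fits[model] = likelihood.fit_mle(
            model, series, init=init, n_starts=config.n_starts,
            seed=(base_seed + 200 + j) % (2 ** 31))

    probs = bayes.model_probabilities(evidences)
    weights = likelihood.akaike_weights(mle_fits)
    for model in MODELS:
        tag = model.value
        row[f"prob_{tag}"] = probs[model]
        row[f"weight_{tag}"] = weights[model]
        row[f"logz_{tag}"] = evidences[model].log_z
        row[f"loglik_{tag}"] = mle_fits[model].loglik
        row[f"mle_r_{tag}"] = mle_fits[model].params.r
        row[f"mle_k_{tag}"] = mle_fits[model].params.k
        summ = bayes.posterior_escapement_summary(
            model, draws_by_model[model], series, force=True)
        row[f"bayes_esc_k_{tag}"] = summ.median_frac_k
        row[f"bayes_esc_max_{tag}"] = summ.median_frac_max_biomass
        u = float(escapement_fraction(model, mle_fits[model].params.r)[0])
        row[f"ml_esc_k_{tag}"] = u
        row[f"ml_esc_max_{tag}"] = (u * mle_fits[model].params.k
                                    / series.max_biomass)
        row[f"bayes_median_r_{tag}"] = float(
            np.median(draws_by_model[model].flat[:, 0]))
    return row


@dataclass
class SelectionSummary:
    """Per-series fit table plus the study-level aggregates."""

    table: pd.DataFrame
    config: StudyConfig
    failures: dict[str, str] = field(default_factory=dict)

    def _support_cols(self, track: str) -> list[str]:
        prefix = "prob_" if track == "bayes" else "weight_"
        return [f"{prefix}{m.value}" for m in MODELS]

    def win_fractions(self, track: str) -> dict[Model, float]:
        """Fraction of series each model wins; ties share credit equally."""
        cols = self._support_cols(track)
        vals = self.table[cols].to_numpy()
        credit = np.zeros(len(MODELS))
        for rowvals in vals:
            winners = rowvals >= rowvals.max() - self.config.tie_tol
            credit += winners / winners.sum()
        credit /= len(vals)
        return {m: float(c) for m, c in zip(MODELS, credit)}

    def top_support(self, track: str) -> np.ndarray:
        return self.table[self._support_cols(track)].to_numpy().max(axis=1)

    def frac_top_above_threshold(self, track: str) -> float:
        top = self.top_support(track)
        return float(np.mean(top > self.config.support_threshold))

    def median_top_support(self, track: str) -> float:
        return float(np.median(self.top_support(track)))

    def most_conservative_fractions(self, track: str, scale: str,
                                    ) -> dict[Model, float]:
        """Which model recommends the highest escapement, per scale.

        ``scale`` is 'k' (fraction of fitted carrying capacity) or 'max'
        (fraction of maximum observed biomass).  Ties share credit.
        """
        prefix = "bayes_esc" if track == "bayes" else "ml_esc"
        cols = [f"{prefix}_{scale}_{m.value}" for m in MODELS]
        vals = self.table[cols].to_numpy()
        credit = np.zeros(len(MODELS))
        for rowvals in vals:
            winners = rowvals >= rowvals.max() - self.config.tie_tol
            credit += winners / winners.sum()
        credit /= len(vals)
        return {m: float(c) for m, c in zip(MODELS, credit)}

    def frac_hockey_stick_above_b60(self, track: str,
                                    denominator: str = "all") -> float:
        """Fraction of series whose Hockey-Stick escapement exceeds 0.6 k.

        ``denominator`` is 'all' (all series) or 'most_conservative' (only
        series where Hockey-Stick is the most conservative model on the
        k scale) — the study text is ambiguous between the two, so both
        are available.
        """
        prefix = "bayes_esc" if track == "bayes" else "ml_esc"
        hs = self.table[f"{prefix}_k_{Model.HOCKEY_STICK.value}"].to_numpy()
        mask = np.ones(len(hs), dtype=bool)
        if denominator == "most_conservative":
            cols = [f"{prefix}_k_{m.value}" for m in MODELS]
            vals = self.table[cols].to_numpy()
            hs_idx = list(MODELS).index(Model.HOCKEY_STICK)
            mask = vals.argmax(axis=1) == hs_idx
            if not mask.any():
                return float("nan")
        return float(np.mean(hs[mask] > self.config.b60_fraction))

    def aggregate(self) -> dict:
        out: dict = {"n_series": int(len(self.table)),
                     "n_failures": len(self.failures)}
        for track in ("bayes", "ml"):
            out[f"win_fractions_{track}"] = {
                m.value: v for m, v in self.win_fractions(track).items()}
            out[f"frac_top_above_095_{track}"] = \
                self.frac_top_above_threshold(track)
            out[f"median_top_support_{track}"] = \
                self.median_top_support(track)
            for scale in ("k", "max"):
                out[f"most_conservative_{scale}_{track}"] = {
                    m.value: v for m, v in
                    self.most_conservative_fractions(track, scale).items()}
            out[f"frac_hs_above_b60_{track}_all"] = \
                self.frac_hockey_stick_above_b60(track, "all")
            out[f"frac_hs_above_b60_{track}_most_conservative"] = \
                self.frac_hockey_stick_above_b60(track, "most_conservative")
        return out


def model_recovery_experiment(n_per_model: int = 10, n_base: int = 10,
                              seed: int = 1,
                              config: StudyConfig = StudyConfig(),
                              ) -> pd.DataFrame:
    """Simulate-and-refit validation: can either track find the true model?

    Synthetic base fisheries stand in for observed assessment series; each
    is fitted by MCMC under all three models, and the fitted posteriors
    seed ``n_per_model`` simulated datasets per generating model (initial
    biomass, harvest-proportion pool and length borrowed from a random
    base series; parameters from the final chain value).  Every simulated
    dataset is then fitted under all three candidate models by both
    tracks.  Returns one row per dataset with the generating model, the
    winner under each track, and the full support vectors.
    """
    from .synthetic import generate_base_fishery, make_validation_experiment

    base = [generate_base_fishery(seed=seed * 101 + i)[0]
            for i in range(n_base)]
    draws_map = {}
    for i, b in enumerate(base):
        for j, model in enumerate(MODELS):
            mcmc = replace(config.mcmc,
                           seed=(seed * 1000 + i * 10 + j) % (2 ** 31))
            draws_map[(b.id, model)] = bayes.sample_posterior(model, b, mcmc)

    datasets = make_validation_experiment(base, draws_map,
                                          n_per_model=n_per_model, seed=seed)
    rows = []
    for idx, (design, series) in enumerate(datasets):
        evidences = {}
        fits = {}
        for j, model in enumerate(MODELS):
            mcmc = replace(config.mcmc,
                           seed=(seed * 5000 + idx * 10 + j) % (2 ** 31))
            draws = bayes.sample_posterior(model, series, mcmc)
            bridge = replace(config.bridge,
                             seed=(seed * 7000 + idx * 10 + j) % (2 ** 31))
            evidences[model] = bayes.log_marginal_likelihood(
                model, series, draws, bridge, force=True)
            best = np.unravel_index(np.argmax(draws.log_post),
                                    draws.log_post.shape)
            fits[model] = likelihood.fit_mle(
                model, series, init=tuple(draws.draws[best]),
                n_starts=config.n_starts,
                seed=(seed * 9000 + idx * 10 + j) % (2 ** 31))
        probs = bayes.model_probabilities(evidences)
        weights = likelihood.akaike_weights(fits)
        row = {"true_model": design.model.value, "T": series.T,
               "winner_bayes": max(probs, key=probs.get).value,
               "winner_ml": max(weights, key=weights.get).value}
        for m in MODELS:
            row[f"prob_{m.value}"] = probs[m]
            row[f"weight_{m.value}"] = weights[m]
        rows.append(row)
    return pd.DataFrame(rows)


def recovery_rates(table: pd.DataFrame) -> dict:
    """Win-rate summaries of a model-recovery table, per track."""
    out: dict = {}
    for track in ("bayes", "ml"):
        col = f"winner_{track}"
        out[f"true_model_win_rate_{track}"] = float(
            (table[col] == table["true_model"]).mean())
        for m in MODELS:
            sub = table[table["true_model"] == m.value]
            out[f"win_rate_{track}_truth_{m.value}"] = float(
                (sub[col] == m.value).mean())
        non_bh = table[table["true_model"] != Model.BEVERTON_HOLT.value]
        out[f"bh_win_rate_under_non_bh_truth_{track}"] = float(
            (non_bh[col] == Model.BEVERTON_HOLT.value).mean())
    return out


def run_study(series_list: list[StockSeries],
              config: StudyConfig = StudyConfig()) -> SelectionSummary:
    """Fit every series under both tracks and summarize model selection.

    Per-series failures are quarantined (logged and reported in
    ``failures``) and the summary is computed on the remainder.  With a
    ``cache_dir`` the per-series records are persisted as JSON, making the
    study resumable; a rerun with the same seed reproduces the same
    summary whether or not the cache was used.
    """
    rows: list[dict] = []
    failures: dict[str, str] = {}
    cache = Path(config.cache_dir) if config.cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    for series in series_list:
        cache_file = (cache / f"{series.id}.json") if cache else None
        if cache_file is not None and cache_file.exists():
            rows.append(json.loads(cache_file.read_text()))
            continue
        try:
            row = analyze_series(series, config)
        except Exception as err:  # noqa: BLE001 - quarantine, keep going
            logger.exception("series %r failed", series.id)
            failures[series.id] = f"{type(err).__name__}: {err}"
            continue
        rows.append(row)
        if cache_file is not None:
            cache_file.write_text(json.dumps(row))
    table = pd.DataFrame(rows)
    return SelectionSummary(table=table, config=config, failures=failures)


def conservativeness_report(summary: SelectionSummary) -> pd.DataFrame:
    """Long-form table of conservativeness aggregates.

    One row per (track, scale, model) with the fraction of series in which
    the model recommends the highest escapement, plus the Hockey-Stick
    above-B60 fractions under both denominators.  Exact ties are flagged.
    """
    records = []
    for track in ("bayes", "ml"):
        for scale in ("k", "max"):
            fracs = summary.most_conservative_fractions(track, scale)
            prefix = "bayes_esc" if track == "bayes" else "ml_esc"
            cols = [f"{prefix}_{scale}_{m.value}" for m in MODELS]
            vals = summary.table[cols].to_numpy()
            n_ties = int(np.sum(
                (vals >= vals.max(axis=1, keepdims=True)
                 - summary.config.tie_tol).sum(axis=1) > 1))
            for m in MODELS:
                records.append({
                    "track": track, "scale": scale, "model": m.value,
                    "most_conservative_fraction": fracs[m],
                    "n_tied_series": n_ties})
        records.append({
            "track": track, "scale": "k", "model": "hockey_stick_above_b60",
            "most_conservative_fraction":
                summary.frac_hockey_stick_above_b60(track, "all"),
            "n_tied_series": 0})
        records.append({
            "track": track, "scale": "k",
            "model": "hockey_stick_above_b60_given_most_conservative",
            "most_conservative_fraction":
                summary.frac_hockey_stick_above_b60(track,
                                                    "most_conservative"),
            "n_tied_series": 0})
    return pd.DataFrame.from_records(records)


def render_figures(summary: SelectionSummary, outdir: str | Path,
                   draws_by_series: dict | None = None) -> list[Path]:
    """Write the study's standard figures (PNG) and their backing CSVs.

    Produces a stacked-bar model-support chart sorted by series length, a
    histogram of best-model support per track, fitted-r histograms, and
    escapement histograms on both scales.  Returns the created paths; an
    empty summary produces nothing but a warning.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    if summary.table.empty:
        logger.warning("empty summary: no figures rendered")
        return []
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    tbl = summary.table.sort_values("T").reset_index(drop=True)
    colors = {"hockey_stick": "tab:green", "beverton_holt": "tab:blue",
              "ricker": "tab:red"}

    # stacked support bars, one panel per track
    fig, axes = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
    for ax, prefix, title in zip(
            axes, ("prob_", "weight_"),
            ("Bayesian model probability", "Akaike weight")):
        bottom = np.zeros(len(tbl))
        for m in MODELS:
            vals = tbl[f"{prefix}{m.value}"].to_numpy()
            ax.bar(np.arange(len(tbl)), vals, bottom=bottom, width=1.0,
                   color=colors[m.value], label=m.value)
            bottom += vals
        ax.set_ylabel(title)
        ax.set_ylim(0, 1)
    axes[0].legend(loc="upper right", fontsize=8)
    axes[1].set_xlabel("series (sorted by length)")
    p = outdir / "model_support.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, track, title in zip(axes, ("bayes", "ml"),
                                ("model probability", "Akaike weight")):
        ax.hist(summary.top_support(track), bins=np.linspace(1 / 3, 1, 21))
        ax.set_xlabel(f"best-model {title}")
    p = outdir / "best_support_hist.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    for row_axes, prefix, title in zip(
            axes, ("bayes_esc", "ml_esc"), ("posterior median", "MLE")):
        for ax, scale, lab in zip(row_axes, ("k", "max"),
                                  ("s*/k", "s*/max biomass")):
            for m in MODELS:
                ax.hist(tbl[f"{prefix}_{scale}_{m.value}"],
                        bins=np.linspace(0, 1.2, 25), alpha=0.55,
                        color=colors[m.value], label=m.value)
            ax.set_xlabel(f"{lab} ({title})")
        row_axes[0].legend(fontsize=7)
    p = outdir / "escapement_hists.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    csv_path = outdir / "summary_table.csv"
    tbl.to_csv(csv_path, index=False)
    paths.append(csv_path)
    agg_path = outdir / "aggregates.json"
    agg_path.write_text(json.dumps(summary.aggregate(), indent=2))
    paths.append(agg_path)
    return paths
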