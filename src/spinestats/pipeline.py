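"""End-to-end orchestration: load or simulate a study, run the spatial
(K-function / CSR / q-value) analysis and the categorical (log-linear + MLR)
analysis, and write report tables and figures.

Spatial tests run per dendrite tree (each tree is its own linear network);
categorical models pool spines per experiment.  Every output directory gets
a ``config.json`` echo with the resolved settings and seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import csr, categorical, neighbors, synthetic
from .exceptions import ValidationError
from .io import read_annotations
from .kfunction import default_t_grid, empirical_k

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_dir: str | None = None  # directory with manifest.json, SWC + CSV
    study: synthetic.StudySpec | None = None  # or generate in memory
    nsim: int = 1000
    variant: str = "ang"
    t_grid_points: int = 512
    sd_breaks: tuple[float, ...] | None = None
    n_per_type: int = 200
    border_margin: float = 10.0
    seed: int = 0
    out_dir: str = "spinestats_out"
    n_example_plots: int = 3
    qvalue_method: str = "storey"


def load_patterns(config: PipelineConfig):
    """Patterns from the input directory's manifest, or a fresh synthetic study."""
    if config.input_dir is not None:
        root = Path(config.input_dir)
        manifest = json.loads((root / "manifest.json").read_text())
        patterns = []
        for entry in manifest["dendrites"]:
            pat = read_annotations(root / entry["swc"], root / entry["spines"])
            pat.dendrite_id = entry["dendrite_id"]
            if entry.get("window"):
                pat.window = tuple(entry["window"])
            patterns.append(pat)
        return patterns
    if config.study is not None:
        return synthetic.generate_study(config.study)
    raise ValidationError("config needs either input_dir or a study spec")


def _echo_config(config: PipelineConfig, out: Path) -> None:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))

    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(dataclasses.asdict(config), default=enc, indent=2))


def run_spatial(config: PipelineConfig):
    """Per-dendrite CSR tests, batch q-values, p-value histograms, and
    Q-Q / K-envelope figures for a seeded sample of dendrites."""
    out = Path(config.out_dir)
    _echo_config(config, out)
    patterns = load_patterns(config)
    if not patterns:
        raise ValidationError("no dendrites to analyze")
    rng = np.random.default_rng(config.seed)
    batch = csr.csr_test_batch(
        patterns,
        nsim=config.nsim,
        rng=rng,
        variant=config.variant,
        qvalue_method=config.qvalue_method,
    )
    table = batch.as_dataframe()
    meta = pd.DataFrame(
        [
            dict(dendrite_id=p.dendrite_id, div=p.spines[0].div, experiment=p.spines[0].experiment)
            for p in patterns
            if p.n >= 2
        ]
    )
    table = table.merge(meta, on="dendrite_id")
    table.to_csv(out / "csr_tests.csv", index=False)

    # p-value histograms per DIV / experiment
    fig, axes = plt.subplots(
        len(table["experiment"].unique()),
        len(table["div"].unique()),
        squeeze=False,
        figsize=(9, 6),
    )
    for i, exp in enumerate(sorted(table["experiment"].unique())):
        for j, div in enumerate(sorted(table["div"].unique())):
            sub = table[(table.experiment == exp) & (table.div == div)]
            ax = axes[i][j]
            ax.hist(sub["p"], bins=np.linspace(0, 1, 11), color="gray")
            ax.axvline(0.05, color="red")
            ax.set_title(f"EXP{exp} DIV{div}", fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "pvalue_histograms.png", dpi=120)
    plt.close(fig)

    # Q-Q and K+envelope figures for a seeded random sample of dendrites
    plot_rng = np.random.default_rng(config.seed + 1)
    eligible = [p for p in patterns if p.n >= 2]
    k_plot = min(config.n_example_plots, len(eligible))
    sample_idx = plot_rng.choice(len(eligible), size=k_plot, replace=False)
    for idx in sample_idx:
        pat = eligible[idx]
        qq = csr.qq_points(pat)
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
        ax1.plot(qq.theoretical, qq.observed, "ko", ms=3)
        lim = max(qq.theoretical.max(), qq.observed.max())
        ax1.plot([0, lim], [0, lim], "r-")
        ax1.set_xlabel("theoretical SD quantile (μm)")
        ax1.set_ylabel("observed SD quantile (μm)")
        grid = default_t_grid(pat, n_points=config.t_grid_points)
        env = csr.pointwise_envelope(
            pat.network, pat.n, max(config.nsim, 20), grid, rng=plot_rng, variant=config.variant
        )
        est = empirical_k(pat, grid, variant=config.variant)
        ax2.fill_between(grid, env.lower, env.upper, color="0.85")
        ax2.plot(grid, est.k_theo, "r-", label="CSR")
        ax2.plot(grid, est.k_hat, "k-", label="observed")
        ax2.set_xlabel("t (μm)")
        ax2.set_ylabel("K(t)")
        ax2.legend(fontsize=7)
        fig.suptitle(pat.dendrite_id, fontsize=9)
        fig.tight_layout()
        fig.savefig(out / f"kfun_{pat.dendrite_id}.png", dpi=120)
        plt.close(fig)
    return table


def run_categorical(config: PipelineConfig):
    """Four-way log-linear stepwise fit, chi-square screens, and the
    neighbor-type MLR with prediction probabilities and Bayes factors."""
    out = Path(config.out_dir)
    _echo_config(config, out)
    patterns = load_patterns(config)
    all_spines = [s for p in patterns for s in p.spines]
    if not all_spines:
        raise ValidationError("no spines to analyze")
    rng = np.random.default_rng(config.seed)

    binned = categorical.bin_features(all_spines, sd_breaks=config.sd_breaks)
    features_by_exp = {}
    reports = {}
    experiments = sorted({s.experiment for s in all_spines})

    # experiment × type table and chi-square screen
    frame = binned.frame
    exp_type = pd.crosstab(frame["experiment"], frame["type"])
    exp_type.to_csv(out / "type_by_experiment.csv")
    if exp_type.shape[0] >= 2:
        stat, df_, p = categorical.chi_square_2way(exp_type.to_numpy())
        reports["exp_type_chi2"] = dict(statistic=stat, df=df_, p=p)

    # per-experiment stepwise log-linear model
    step_rows = []
    for exp in experiments:
        sub = frame[frame["experiment"] == exp]
        table = categorical.build_contingency(sub, dims=("div", "type", "bo", "sd"))
        trace = categorical.stepwise_aic(table)
        drop = trace.drop_one.copy()
        drop.insert(0, "experiment", exp)
        step_rows.append(drop)
        reports[f"exp{exp}_final_terms"] = list(trace.final.terms)
        reports[f"exp{exp}_final_aic"] = trace.final.aic
    pd.concat(step_rows).to_csv(out / "stepwise_drop_one.csv", index=False)

    # neighbor features + per-experiment chi-square screen and MLR
    feats = neighbors.build_neighbor_features(patterns)
    screen_rows, coef_rows, prob_rows, bf_rows = [], [], [], []
    for exp in experiments:
        mask = feats.meta["experiment"].to_numpy() == exp
        idx = np.flatnonzero(mask)
        sub_y = feats.y[idx]
        # type vs N1/N2/N3 chi-square screen over all spines of the experiment
        for nb in range(3):
            nb_type = np.where(
                feats.X[idx, 2 * nb] == 1, 0, np.where(feats.X[idx, 2 * nb + 1] == 1, 1, 2)
            )
            tab = pd.crosstab(sub_y, nb_type).to_numpy()
            if tab.shape[0] >= 2 and tab.shape[1] >= 2:
                stat, df_, p = categorical.chi_square_2way(tab)
                screen_rows.append(
                    dict(experiment=exp, predictor=f"N{nb + 1}", chi2=stat, df=df_, p=p)
                )
        # balanced sample and MLR
        sub_feats = neighbors.NeighborFeatures(
            X=feats.X[idx],
            y=feats.y[idx],
            distances=feats.distances[idx],
            meta=feats.meta.iloc[idx].reset_index(drop=True),
        )
        window = None
        for p_ in patterns:
            if p_.spines and p_.spines[0].experiment == exp and p_.window:
                window = p_.window  # windows coincide per experiment fixture
        counts = neighbors.eligible_counts(sub_feats, window, margin=config.border_margin)
        n_per = min(config.n_per_type, min(counts.values()))
        if n_per < 1:
            logger.warning("experiment %s lacks a spine type entirely; skipping MLR", exp)
            continue
        if n_per < config.n_per_type:
            logger.warning(
                "experiment %s: only %d spines of the scarcest type; balanced sample reduced",
                exp,
                n_per,
            )
        sample = neighbors.sample_balanced(
            sub_feats, window, n_per, margin=config.border_margin, rng=rng
        )
        model = neighbors.fit_mlr(sub_feats, indices=sample.indices)
        for row_name, beta in (("stubby", model.beta_stubby), ("thin", model.beta_thin)):
            coef_rows.append(
                dict(experiment=exp, category=row_name)
                | dict(zip(("intercept",) + neighbors.FEATURE_NAMES, beta))
            )
        priors_counts = np.bincount(sub_feats.y, minlength=3).astype(float)
        priors = {
            t: priors_counts[c] / priors_counts.sum() for t, c in neighbors.TYPE_CODES.items()
        }
        for div in sorted({int(d) for d in sub_feats.meta["div"]}):
            for nb_type in neighbors.TYPE_CODES:
                X = neighbors.neighbor_vector(nb_type, nb_type, nb_type, div)
                probs = neighbors.predict_probs(model, X)
                prob_rows.append(
                    dict(experiment=exp, div=div, neighborhood=nb_type, **probs)
                )
                bf = neighbors.bayes_factor(model, X, priors)
                bf_rows.append(
                    dict(experiment=exp, div=div, neighborhood=nb_type, **{f"bf_{k}": v for k, v in bf.items()})
                )
        features_by_exp[exp] = sub_feats

    pd.DataFrame(screen_rows).to_csv(out / "type_neighbor_chi2.csv", index=False)
    pd.DataFrame(coef_rows).to_csv(out / "mlr_coefficients.csv", index=False)
    pd.DataFrame(prob_rows).to_csv(out / "mlr_prediction_probs.csv", index=False)
    pd.DataFrame(bf_rows).to_csv(out / "mlr_bayes_factors.csv", index=False)
    (out / "categorical_report.json").write_text(json.dumps(reports, indent=2, default=float))
    return reports
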