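"""Leave-one-family-out benchmark of weighted vs. conventional models.

Within every environment each family serves exactly once as the testing set
while the remaining families form the training set; the whole weighting
procedure (fictitious response, binary Lasso, penalty weights) is rerun
inside every fold from genotypes alone, so nothing about the testing
family's phenotypes can leak into training.  Prediction error is reported as
NRMSE = RMSE / mean(observed testing values); 0 means perfect predictions.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import weighting
from .config import RunConfig, derive_seed
from .io import PhenotypeTable, align_phenotypes
from .solver import GenotypeMatrix

logger = logging.getLogger(__name__)


def nrmse(y_obs, y_pred, normalize: str = "mean") -> float:
    """Root mean squared error normalized by the observed values.

    ``normalize="mean"`` (default) divides by the mean of the observed
    testing values and errors out when that mean is within 1e-12 of zero
    (traits centered near zero should use the "sd" or "range" variant).
    """
    y_obs = np.asarray(y_obs, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_obs.shape != y_pred.shape or y_obs.ndim != 1 or y_obs.size < 1:
        raise ValueError("y_obs and y_pred must be equal-length vectors")
    rmse = float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))
    if normalize == "mean":
        denom = float(np.mean(y_obs))
        if abs(denom) <= 1e-12:
            raise ValueError("mean of observations is ~0: mean-normalized "
                             "NRMSE is undefined (try normalize='sd' or "
                             "'range')")
        denom = abs(denom)
    elif normalize == "sd":
        denom = float(np.std(y_obs))
        if denom <= 1e-12:
            raise ValueError("observations are constant: sd-normalized "
                             "NRMSE is undefined")
    elif normalize == "range":
        denom = float(np.ptp(y_obs))
        if denom <= 1e-12:
            raise ValueError("observations are constant: range-normalized "
                             "NRMSE is undefined")
    else:
        raise ValueError("normalize must be 'mean', 'sd' or 'range'")
    return rmse / denom


@dataclass
class FamilySplit:
    """One leave-one-family-out fold within one environment."""

    env: object
    test_family: object
    train_idx: np.ndarray
    test_idx: np.ndarray


def lofo_splits(families, envs=None) -> list[FamilySplit]:
    """One split per (environment, family): that family is the testing set.

    ``families`` and ``envs`` are per-record labels (same length); a single
    environment is assumed when ``envs`` is None.  Indices refer to positions
    in those label vectors.
    """
    families = np.asarray(families, dtype=object)
    if envs is None:
        envs = np.zeros(families.size, dtype=object)
    envs = np.asarray(envs, dtype=object)
    if envs.size != families.size:
        raise ValueError("families and envs must have equal length")
    splits = []
    for env in sorted(set(envs), key=str):
        in_env = np.flatnonzero(envs == env)
        fams = sorted(set(families[in_env]), key=str)
        if len(fams) < 2:
            raise ValueError(f"environment {env!r} has a single family; "
                             "leave-one-family-out is undefined")
        for fam in fams:
            mask = families[in_env] == fam
            splits.append(FamilySplit(env=env, test_family=fam,
                                      train_idx=in_env[~mask],
                                      test_idx=in_env[mask]))
    return splits


@dataclass
class EvaluationReport:
    """Long-format fold records plus summary views.

    ``records`` has one row per (env, test family, model, trait) with its
    NRMSE; ``diagnostics`` one row per fold with the binary-Lasso lambda and
    a digest of the penalty weights (leakage audits compare these digests).
    """

    records: pd.DataFrame
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary_by_trait(self) -> pd.DataFrame:
        """One row per (dataset, model, trait), folds pooled across envs."""
        g = self.records.groupby(["dataset", "model", "trait"])["nrmse"]
        out = g.agg(NRMSE="mean", NRMSE_SD=lambda s: s.std(ddof=1),
                    NRMSE_SE=lambda s: s.std(ddof=1) / np.sqrt(len(s)))
        return out.reset_index().rename(columns={
            "dataset": "Dataset", "model": "Model", "trait": "Trait"})

    def summary_overall(self) -> pd.DataFrame:
        """One row per model pooled over everything."""
        g = self.records.groupby("model")["nrmse"]
        out = g.agg(NRMSE_Mean="mean",
                    NRMSE_Mean_SD=lambda s: s.std(ddof=1))
        return out.reset_index().rename(columns={"model": "Model"})

    def improvements(self) -> pd.DataFrame:
        """Relative gain of each weighted model over its counterpart.

        Percentage convention: ``100 * (NRMSE_base - NRMSE_weighted) /
        NRMSE_weighted`` (positive = weighted model better).
        """
        rows = []
        overall = self.summary_overall().set_index("Model")["NRMSE_Mean"]
        per_trait = self.summary_by_trait()
        for wm in weighting.WEIGHTED_MODELS:
            base = wm[1:]
            if wm in overall.index and base in overall.index:
                rows.append({"Base": base, "Weighted": wm, "Trait": "(all)",
                             "NRMSE_Base": overall[base],
                             "NRMSE_Weighted": overall[wm],
                             "Improvement_pct": 100.0 * (overall[base] - overall[wm])
                             / overall[wm]})
            sub = per_trait[per_trait["Model"].isin([base, wm])]
            for trait, tdf in sub.groupby("Trait"):
                vals = tdf.set_index("Model")["NRMSE"]
                if base in vals.index and wm in vals.index:
                    rows.append({"Base": base, "Weighted": wm, "Trait": trait,
                                 "NRMSE_Base": vals[base],
                                 "NRMSE_Weighted": vals[wm],
                                 "Improvement_pct": 100.0 * (vals[base] - vals[wm])
                                 / vals[wm]})
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        """Dump the long records plus the two summary tables as CSV."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "records.csv", index=False)
        self.summary_by_trait().to_csv(outdir / "summary_by_trait.csv",
                                       index=False)
        self.summary_overall().to_csv(outdir / "summary_overall.csv",
                                      index=False)
        self.improvements().to_csv(outdir / "improvements.csv", index=False)
        if len(self.diagnostics):
            self.diagnostics.to_csv(outdir / "fold_diagnostics.csv",
                                    index=False)


def _weights_digest(weights) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(weights.raw).tobytes())
    h.update(np.ascontiguousarray(weights.excluded_mask).tobytes())
    return h.hexdigest()[:16]


def run_benchmark(geno: GenotypeMatrix, pheno: PhenotypeTable,
                  config: RunConfig | None = None,
                  dataset: str = "dataset") -> EvaluationReport:
    """Leave-one-family-out benchmark over every environment and trait.

    For each fold the weighted models recompute the penalty weights from the
    fold's genotypes (one binary Lasso per fold, shared across weighted
    models and traits); every model then selects lambda by CV inside the
    training families and is scored by NRMSE on the held-out family.
    """
    cfg = config or RunConfig()
    df, geno_rows = align_phenotypes(geno, pheno)
    traits = list(cfg.traits) if cfg.traits else list(pheno.trait_names)
    missing = [t for t in traits if t not in df.columns]
    if missing:
        raise ValueError(f"traits not in phenotype table: {missing}")
    for t in traits:
        if not np.issubdtype(df[t].dtype, np.number):
            raise ValueError(f"trait column '{t}' is not numeric")
    logger.info("benchmark: dataset=%s seed=%d config=%s folds=%d models=%s",
                dataset, cfg.seed, cfg.config_hash(), cfg.cv_folds,
                ",".join(cfg.models))

    splits = lofo_splits(df["family"].to_numpy(), df["env"].to_numpy())
    need_weights = any(m in weighting.WEIGHTED_MODELS for m in cfg.models)
    records, diags = [], []
    for sp in splits:
        X_trn = geno.values[geno_rows[sp.train_idx]]
        X_tst = geno.values[geno_rows[sp.test_idx]]
        weights = None
        if need_weights:
            bseed = derive_seed(cfg.seed, dataset, sp.env, sp.test_family,
                                "binary")
            bfit = weighting.fit_binary_lasso(X_trn, X_tst, cfg, seed=bseed)
            weights = weighting.compute_weights(
                bfit.beta_bin, policy=cfg.zero_coef_policy, cap=cfg.cap)
            diags.append({
                "dataset": dataset, "env": sp.env,
                "test_family": sp.test_family,
                "lambda_bin": bfit.lambda_bin,
                "n_selected": int(np.count_nonzero(bfit.beta_bin)),
                "n_excluded": int(weights.excluded_mask.sum()),
                "weights_digest": _weights_digest(weights)})
        for model in cfg.models:
            for trait in traits:
                y_trn = df[trait].to_numpy()[sp.train_idx]
                y_tst = df[trait].to_numpy()[sp.test_idx]
                # seed keyed by the base model so a weighted model and its
                # counterpart select lambda on identical CV folds
                mseed = derive_seed(cfg.seed, dataset, sp.env,
                                    sp.test_family, model.lstrip("w"), trait)
                if model in weighting.WEIGHTED_MODELS:
                    fit, preds = weighting.fit_weighted_model(
                        X_trn, y_trn, X_tst, model, cfg, seed=mseed,
                        weights=weights)
                else:
                    fit, preds = weighting.fit_unweighted_model(
                        X_trn, y_trn, X_tst, model, cfg, seed=mseed)
                records.append({
                    "dataset": dataset, "env": sp.env,
                    "test_family": sp.test_family, "model": model,
                    "trait": trait,
                    "nrmse": nrmse(y_tst, preds, cfg.normalize),
                    "lambda": fit.lam, "n_nonzero": fit.n_nonzero})
    return EvaluationReport(records=pd.DataFrame(records),
                            diagnostics=pd.DataFrame(diags))


def plot_report(report: EvaluationReport, path) -> None:
    """Bar chart of mean NRMSE per model and trait, one panel per dataset."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = report.summary_by_trait()
    datasets = summary["Dataset"].unique()
    fig, axes = plt.subplots(1, len(datasets),
                             figsize=(5 * len(datasets), 4), squeeze=False)
    for ax, ds in zip(axes[0], datasets):
        sub = summary[summary["Dataset"] == ds]
        piv = sub.pivot(index="Model", columns="Trait", values="NRMSE")
        piv.plot.bar(ax=ax, title=str(ds), ylabel="NRMSE", rot=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
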