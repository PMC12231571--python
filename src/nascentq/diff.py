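"""Differential transcription under multifactor designs.

Counts from promoter-proximal, gene-body or enhancer regions are fitted
with a negative-binomial GLM on the full design (condition of interest
plus covariates such as batch), tested with a Wald test on the requested
contrast and corrected with Benjamini–Hochberg.  The engine is PyDESeq2;
user-supplied normalization factors (e.g. spike-in derived) replace the
median-of-ratios size factors when given, and the same factors are used
for every region so promoter, body and enhancer scales agree.

A permutation background is also provided: per feature, the pooled total
count is redistributed across samples in proportion to library size,
mimicking a read-level permutation between conditions at count level,
and the observed |log2 fold change| is compared with the permuted ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

ENGINE = "pydeseq2"
DEFAULT_FDR_CUT = 0.05
DEFAULT_LFC_CUT = 0.3


@dataclass
class DesignTable:
    """Sample sheet: one row per sample, a condition column, optional
    covariates (e.g. batch), optionally an alignment-path column."""

    frame: pd.DataFrame
    condition: str = "condition"
    covariates: tuple[str, ...] = ()
    path_column: str | None = None

    def __post_init__(self) -> None:
        df = self.frame
        if "sample_id" not in df.columns:
            raise ConfigError("design table needs a 'sample_id' column")
        if df["sample_id"].duplicated().any():
            raise ConfigError("duplicate sample_id in design table")
        for col in (self.condition, *self.covariates):
            if col not in df.columns:
                raise ConfigError(f"design table lacks column {col!r}")
            if df[col].isna().any():
                raise ConfigError(f"design column {col!r} has missing cells")
        if len(df) < 2:
            raise ConfigError("design table needs at least 2 samples")
        if df[self.condition].nunique() < 2:
            raise ConfigError(f"condition column {self.condition!r} needs >=2 levels")
        self.frame = df.set_index(df["sample_id"].astype(str), drop=False)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    def samples_of(self, level: str) -> list[str]:
        return list(self.frame.index[self.frame[self.condition].astype(str) == level])

    def check_not_confounded(self) -> None:
        """Fatal when the condition is aliased with a covariate (the model
        matrix would be rank deficient)."""
        cols = [self.condition, *self.covariates]
        dummies = pd.get_dummies(
            self.frame[cols].astype(str), drop_first=True, dtype=float
        )
        mat = np.column_stack([np.ones(len(self.frame)), dummies.to_numpy()])
        if np.linalg.matrix_rank(mat) < mat.shape[1]:
            raise ConfigError(
                "design is confounded: condition "
                f"{self.condition!r} is aliased with covariate(s) {self.covariates}"
            )

    @classmethod
    def read(
        cls,
        path: str | Path,
        condition: str = "condition",
        covariates: tuple[str, ...] = (),
        path_column: str | None = None,
    ) -> "DesignTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        return cls(df, condition=condition, covariates=covariates, path_column=path_column)


def fit_differential(
    counts: pd.DataFrame,
    design: DesignTable,
    contrast: tuple[str, str],
    factors: pd.Series | None = None,
    allow_no_replicates: bool = False,
) -> pd.DataFrame:
    """NB-GLM differential test of ``contrast = (level_b, level_a)``.

    Parameters
    ----------
    counts : DataFrame, features x samples (integer).
    design : DesignTable whose rows match the count columns.
    contrast : (treatment level, reference level) of the condition column;
        log2 fold changes are level_b over level_a.
    factors : per-sample normalization factors; when None, median-of-ratios
        factors are fitted on ``counts`` itself.

    Returns a DataFrame with feature, base_mean, log2fc, pvalue, fdr; all
    features with at least one nonzero count are tested, all-zero features
    are excluded and reported in the ``tested`` column of the attrs.
    """
    level_b, level_a = contrast
    design.check_not_confounded()
    samples = design.samples
    missing = [s for s in samples if s not in counts.columns]
    if missing:
        raise ConfigError(f"count matrix lacks design samples: {missing}")
    counts = counts[samples]
    levels = design.frame[design.condition].astype(str)
    for lvl in (level_a, level_b):
        n = (levels == lvl).sum()
        if n == 0:
            raise ConfigError(f"contrast level {lvl!r} absent from design")
        if n < 2 and not allow_no_replicates:
            raise ConfigError(
                f"condition level {lvl!r} has a single replicate; pass "
                "allow_no_replicates to proceed"
            )
    nonzero = counts.sum(axis=1) > 0
    dropped = counts.index[~nonzero]
    mat = counts.loc[nonzero].T.astype(int)  # samples x features for the engine

    import warnings

    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    class _FixedFactorDDS(DeseqDataSet):
        """DeseqDataSet honouring externally supplied size factors."""

        _fixed_sf: np.ndarray | None = None

        def fit_size_factors(self, *args, **kwargs):  # noqa: D102
            if self._fixed_sf is None:
                return super().fit_size_factors(*args, **kwargs)
            self.obs["size_factors"] = self._fixed_sf
            self.layers["normed_counts"] = self.X / self._fixed_sf[:, None]
            self.var["_normed_means"] = self.layers["normed_counts"].mean(axis=0)

    meta = design.frame.loc[samples, [design.condition, *design.covariates]].astype(str)
    terms = " + ".join([*design.covariates, design.condition])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = _FixedFactorDDS(
            counts=mat,
            metadata=meta,
            design=f"~{terms}",
            refit_cooks=False,
            quiet=True,
        )
        if factors is not None:
            f = np.asarray(pd.Series(factors).loc[samples], dtype=float)
            if (f <= 0).any():
                raise ConfigError("normalization factors must be > 0")
            dds._fixed_sf = f
        dds.deseq2()
        ds = DeseqStats(
            dds,
            contrast=[design.condition, level_b, level_a],
            cooks_filter=False,
            independent_filter=False,
            quiet=True,
        )
        ds.summary()
    res = ds.results_df
    out = pd.DataFrame(
        {
            "feature": res.index,
            "base_mean": res["baseMean"].to_numpy(),
            "log2fc": res["log2FoldChange"].to_numpy(),
            "stat": res["stat"].to_numpy(),
            "pvalue": res["pvalue"].to_numpy(),
            "fdr": res["padj"].to_numpy(),
        }
    ).reset_index(drop=True)
    out.attrs["engine"] = ENGINE
    out.attrs["excluded_all_zero"] = list(map(str, dropped))
    out.attrs["contrast"] = f"{design.condition}:{level_b}_vs_{level_a}"
    if len(dropped):
        logger.info("excluded %d all-zero feature(s) from testing", len(dropped))
    return out


def classify_dysregulated(
    results: pd.DataFrame,
    fdr_cut: float = DEFAULT_FDR_CUT,
    lfc_cut: float = DEFAULT_LFC_CUT,
) -> pd.Series:
    """Label features up/down/unchanged with strict threshold inequalities.

    A feature is called only when FDR < fdr_cut AND |log2fc| > lfc_cut;
    boundary values (FDR exactly at the cut) stay 'unchanged'.
    """
    if fdr_cut < 0 or lfc_cut < 0:
        raise ConfigError("classification thresholds must be >= 0")
    fdr = results["fdr"].to_numpy(dtype=float)
    lfc = results["log2fc"].to_numpy(dtype=float)
    sig = np.nan_to_num(fdr, nan=1.0) < fdr_cut
    labels = np.where(
        sig & (lfc > lfc_cut), "up", np.where(sig & (lfc < -lfc_cut), "down", "unchanged")
    )
    return pd.Series(labels, index=results.index, name="class")


def permutation_null(
    counts: pd.DataFrame,
    design: DesignTable,
    contrast: tuple[str, str],
    factors: pd.Series | None = None,
    n_perm: int = 100,
    seed: int = 0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Empirical per-feature p-values from a count-level read permutation.

    For each permutation every feature's pooled total is redistributed
    across samples multinomially with probabilities proportional to
    library size — the count-level equivalent of shuffling reads between
    the conditions.  The statistic is |log2 fold change| of normalized
    condition means (with a pseudocount); empirical
    p = (1 + #{perm >= observed}) / (1 + n_perm), so the smallest
    attainable p with ``n_perm`` permutations is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if n_perm < 20:
        logger.warning("n_perm=%d gives coarse p-value resolution", n_perm)
    level_b, level_a = contrast
    samples = design.samples
    counts = counts[samples]
    idx_a = [samples.index(s) for s in design.samples_of(level_a)]
    idx_b = [samples.index(s) for s in design.samples_of(level_b)]
    if not idx_a or not idx_b:
        raise ConfigError("both contrast levels need at least one sample")
    mat = counts.to_numpy(dtype=np.int64)
    if factors is None:
        f = np.ones(len(samples))
    else:
        f = np.asarray(pd.Series(factors).loc[samples], dtype=float)
    lib = mat.sum(axis=0).astype(float)
    if lib.sum() == 0:
        raise DataError("empty count matrix")
    probs = lib / lib.sum()

    def statistic(m: np.ndarray) -> np.ndarray:
        normed = m / f
        mean_a = normed[:, idx_a].mean(axis=1)
        mean_b = normed[:, idx_b].mean(axis=1)
        return np.abs(np.log2((mean_b + pseudocount) / (mean_a + pseudocount)))

    obs = statistic(mat)
    rng = np.random.default_rng(seed)
    totals = mat.sum(axis=1)
    exceed = np.zeros(len(totals), dtype=np.int64)
    for _ in range(n_perm):
        perm = np.vstack([rng.multinomial(t, probs) for t in totals])
        exceed += statistic(perm) >= obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame(
        {"feature": counts.index, "observed_abs_log2fc": obs, "perm_pvalue": pvals}
    ).reset_index(drop=True)
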