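"""Method-agreement and heritability statistics.

Three analyses validate an automated scorer against manual scoring and
ask whether the trait is heritable across strains:

* ordinary least-squares regression of automated on manual CI (slope,
  intercept, R²);
* a strain-effect test: the model ``automated ~ manual + strain`` is
  compared against ``automated ~ manual`` by an extra-sum-of-squares
  F test, with per-strain coefficients normalized to a reference strain —
  a significant F would indicate strain-dependent systematic error in the
  automated method;
* broad-sense heritability H² = var_strain / (var_strain + var_residual)
  from a one-way random-effects decomposition of the phenotype, i.e. the
  fraction of total phenotypic variance explained by strain differences.

The default H² backend is the balanced method-of-moments (ANOVA)
estimator; a REML backend (statsmodels MixedLM) is available and agrees
with it in expectation on balanced designs.  Negative variance-component
estimates are truncated at zero so H² stays in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DegenerateFitError, ValidationError


@dataclass(frozen=True)
class AgreementRecord:
    """One plate scored by both methods."""

    strain: str
    compound: str
    manual_ci: float
    automated_ci: float

    def __post_init__(self) -> None:
        if not self.strain or not self.compound:
            raise ValidationError("strain and compound must be non-empty")
        for name in ("manual_ci", "automated_ci"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValidationError(f"{name} out of [-1, 1]: {v}")


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class StrainEffectResult:
    """Per-strain coefficients (normalized to the reference strain) and
    the extra-sum-of-squares F test for any strain effect."""

    reference: str
    estimates: dict[str, tuple[float, float, float]]  # strain -> (est, lo, hi)
    f_stat: float
    df1: int
    df2: int
    p_value: float


@dataclass(frozen=True)
class HeritabilityEstimate:
    h2: float
    var_strain: float
    var_residual: float
    n_strains: int
    n_total: int
    estimator: str


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        {
            "strain": [r.strain for r in records],
            "compound": [r.compound for r in records],
            "manual_ci": [r.manual_ci for r in records],
            "automated_ci": [r.automated_ci for r in records],
        }
    )


def fit_agreement(records) -> RegressionFit:
    """OLS of automated CI on manual CI.

    Raises :class:`DegenerateFitError` when the manual CIs have zero
    variance (the slope is unidentifiable).
    """
    df = _records_frame(records)
    n = len(df)
    if n < 3:
        raise ValidationError(f"need at least 3 records, got {n}")
    x = df["manual_ci"].to_numpy(dtype=float)
    y = df["automated_ci"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateFitError("manual_ci has zero variance; slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    sst = float(np.sum((y - y.mean()) ** 2))
    # a constant response carries no variance to explain: R^2 = 0 by
    # convention rather than statsmodels' 0/0
    r2 = 1.0 - float(model.ssr) / sst if sst > 0 else 0.0
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=r2,
        n=n,
    )


def strain_effect_anova(records, reference: str | None = None) -> StrainEffectResult:
    """Test for strain-dependent systematic error in the automated method.

    Fits ``automated ~ manual + strain`` (strain categorical, treatment
    coding against ``reference``, default the lexicographically first
    strain) and compares it with ``automated ~ manual`` by an
    extra-sum-of-squares F test.  Per-strain estimates come with 95%
    confidence intervals; the reference strain's normalized estimate is
    exactly 0.
    """
    df = _records_frame(records)
    strains = sorted(df["strain"].unique())
    if len(strains) < 2:
        raise ValidationError("need at least 2 strains")
    counts = df["strain"].value_counts()
    thin = [s for s in strains if counts[s] < 2]
    if thin:
        raise ValidationError(f"strains with fewer than 2 records: {thin}")
    if reference is None:
        reference = strains[0]
    elif reference not in strains:
        raise ValidationError(f"reference strain {reference!r} not in data")

    y = df["automated_ci"].to_numpy(dtype=float)
    x = df["manual_ci"].to_numpy(dtype=float)
    others = [s for s in strains if s != reference]
    dummies = np.column_stack(
        [(df["strain"].to_numpy() == s).astype(float) for s in others]
    )
    x_red = np.column_stack([np.ones_like(x), x])
    x_full = np.column_stack([x_red, dummies])

    rank = np.linalg.matrix_rank(x_full)
    if rank < x_full.shape[1]:
        degenerate = [
            s for s in strains if df.loc[df["strain"] == s, "manual_ci"].nunique() == 1
        ]
        raise DegenerateFitError(
            "rank-deficient design for the strain-effect model"
            + (f"; strains with constant manual CI: {degenerate}" if degenerate else "")
        )

    full = sm.OLS(y, x_full).fit()
    red = sm.OLS(y, x_red).fit()
    df1 = len(others)
    df2 = int(full.df_resid)
    if df2 <= 0:
        raise DegenerateFitError("no residual degrees of freedom")
    f_stat = float(((red.ssr - full.ssr) / df1) / (full.ssr / df2))
    p = float(sps.f.sf(f_stat, df1, df2))

    conf = full.conf_int(alpha=0.05)
    estimates: dict[str, tuple[float, float, float]] = {reference: (0.0, 0.0, 0.0)}
    for i, s in enumerate(others):
        j = 2 + i
        estimates[s] = (float(full.params[j]), float(conf[j, 0]), float(conf[j, 1]))
    return StrainEffectResult(
        reference=reference,
        estimates=estimates,
        f_stat=f_stat,
        df1=df1,
        df2=df2,
        p_value=p,
    )


def _phenotype_frame(phenotypes) -> pd.DataFrame:
    if isinstance(phenotypes, pd.DataFrame):
        return phenotypes.rename(
            columns={phenotypes.columns[0]: "strain", phenotypes.columns[1]: "value"}
        )
    return pd.DataFrame(phenotypes, columns=["strain", "value"])


def broad_sense_heritability(
    phenotypes, method: str = "moments"
) -> HeritabilityEstimate:
    """Broad-sense heritability from (strain, phenotype) pairs.

    ``method="moments"`` uses the one-way random-effects ANOVA estimator:
    var_strain = (MS_between - MS_within) / n0 with the standard n0 for
    (possibly unbalanced) group sizes.  ``method="reml"`` fits a random
    intercept per strain by REML.  Negative strain-variance estimates are
    truncated at zero before forming H².
    """
    df = _phenotype_frame(phenotypes)
    groups = df.groupby("strain")["value"]
    sizes = groups.size()
    k = len(sizes)
    n_total = int(sizes.sum())
    if k < 2:
        raise DegenerateFitError("H2 is undefined with a single strain")
    if (sizes < 2).any():
        raise ValidationError(
            f"strains with fewer than 2 replicates: {list(sizes[sizes < 2].index)}"
        )

    if method == "moments":
        grand = df["value"].mean()
        means = groups.mean()
        ssb = float((sizes * (means - grand) ** 2).sum())
        ssw = float(((df["value"] - df["strain"].map(means)) ** 2).sum())
        msb = ssb / (k - 1)
        msw = ssw / (n_total - k)
        n0 = (n_total - float((sizes**2).sum()) / n_total) / (k - 1)
        var_strain = max(0.0, (msb - msw) / n0)
        var_resid = msw
    elif method == "reml":
        model = sm.MixedLM(
            df["value"].to_numpy(dtype=float),
            np.ones((n_total, 1)),
            groups=df["strain"].to_numpy(),
        )
        with np.errstate(all="ignore"):
            result = model.fit(reml=True)
        var_strain = max(0.0, float(np.asarray(result.cov_re)[0, 0]))
        var_resid = float(result.scale)
    else:
        raise ValidationError(f"unknown method {method!r}; use 'moments' or 'reml'")

    total = var_strain + var_resid
    # total == 0 means every value is identical: no variance to partition
    h2 = var_strain / total if total > 0 else 0.0
    return HeritabilityEstimate(
        h2=float(h2),
        var_strain=float(var_strain),
        var_residual=float(var_resid),
        n_strains=k,
        n_total=n_total,
        estimator=method,
    )
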