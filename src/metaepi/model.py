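"""Model/Results interface to the meta-epidemiological pipeline.

Follows the statsmodels convention: a :class:`MetaEpidemiologyModel` is
constructed from data (two DataFrames or two CSV paths), ``fit()``
returns a :class:`MetaEpiResults` object carrying the estimates, their
uncertainties and diagnostics, and ``summary()`` renders the
forest-style table.
"""

from __future__ import annotations

import io as _io

import numpy as np
import pandas as pd

from .pipeline import (
    CHARACTERISTICS,
    MetaEpiResult,
    RunConfig,
    run_all,
    run_characteristic,
)

__all__ = ["MetaEpidemiologyModel", "MetaEpiResults"]


class MetaEpidemiologyModel:
    """Two-step meta-epidemiological model of risk-of-bias effects.

    Parameters
    ----------
    studies : DataFrame
        One row per experimental arm: ``ma_id``, ``study_id``,
        ``arm_id``, ``smd``, ``var`` and one ``rob_<characteristic>``
        column per rated item (values ``low``/``high``/``unclear``/NA).
    mas : DataFrame
        One row per meta-analysis: ``ma_id``, ``expected_direction``
        (``benefit_positive``/``benefit_negative``/``unclear``) and
        optional metadata (``design``, ``topic``).
    config : RunConfig, optional
        Eligibility thresholds, tau² estimator, CI method and robust
        variance type.

    Examples
    --------
    >>> model = MetaEpidemiologyModel(studies, mas)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        studies: pd.DataFrame,
        mas: pd.DataFrame,
        config: RunConfig | None = None,
    ) -> None:
        self.studies = studies.reset_index(drop=True)
        self.mas = mas.reset_index(drop=True)
        self.config = config or RunConfig()

    @classmethod
    def from_csv(
        cls,
        studies_path,
        mas_path,
        config: RunConfig | None = None,
    ) -> "MetaEpidemiologyModel":
        """Build the model from the validated CSV inputs (see
        :func:`metaepi.io.validate_dataset` for the schema)."""
        from .io import validate_dataset

        dataset = validate_dataset(studies_path, mas_path)
        return cls(dataset.studies, dataset.mas, config=config)

    def fit(self, robust: bool = False) -> "MetaEpiResults":
        """Run the two-step analysis for all ten characteristics.

        ``robust=True`` replaces the step-1 standard errors by
        study-clustered CR2 sandwich estimates (the sensitivity
        analysis for multi-arm dependence).
        """
        results = run_all(self.studies, self.mas, config=self.config,
                          robust=robust)
        return MetaEpiResults(self, results, robust=robust)

    def fit_characteristic(
        self, characteristic: str, robust: bool = False
    ) -> MetaEpiResult:
        """Two-step analysis for a single characteristic."""
        return run_characteristic(
            self.studies, self.mas, characteristic,
            config=self.config, robust=robust,
        )


class MetaEpiResults:
    """Fitted results: one pooled DMSD per risk-of-bias characteristic.

    Attributes
    ----------
    results : list of MetaEpiResult
        In canonical characteristic order, length 10; skipped
        characteristics carry a reason instead of an estimate.
    robust : bool
        Whether step-1 standard errors were cluster-robust.
    """

    def __init__(
        self,
        model: MetaEpidemiologyModel,
        results: list[MetaEpiResult],
        robust: bool = False,
    ) -> None:
        self.model = model
        self.results = results
        self.robust = robust

    def __getitem__(self, characteristic: str) -> MetaEpiResult:
        for r in self.results:
            if r.characteristic == characteristic:
                return r
        raise KeyError(characteristic)

    def to_frame(self) -> pd.DataFrame:
        """One row per characteristic: estimate, CI, heterogeneity,
        counts and skip reason."""
        rows = []
        for r in self.results:
            rows.append(
                {
                    "characteristic": r.characteristic,
                    "pooled_dmsd": r.pooled_dmsd,
                    "se": r.se,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "tau2": r.tau2,
                    "i2": r.i2,
                    "n_mas": r.n_mas,
                    "n_arms": r.n_arms,
                    "robust": r.robust,
                    "skipped": r.skipped,
                    "skip_reason": r.skip_reason,
                }
            )
        return pd.DataFrame(rows)

    def per_ma_frame(self) -> pd.DataFrame:
        """Step-1 DMSD estimates: one row per contributing
        meta-analysis per non-skipped characteristic."""
        rows = []
        for r in self.results:
            if r.skipped:
                continue
            for e in r.per_ma:
                rows.append(
                    {
                        "characteristic": r.characteristic,
                        "ma_id": e.ma_id,
                        "dmsd": e.dmsd,
                        "se": e.se,
                        "n_high_unclear": e.n_high_unclear,
                        "n_low": e.n_low,
                        "tau2_residual": e.tau2_residual,
                        "robust": e.robust,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "characteristic", "ma_id", "dmsd", "se",
                "n_high_unclear", "n_low", "tau2_residual", "robust",
            ],
        )

    def summary(self) -> str:
        """Forest-style text table: DMSD (95% CI), I², counts per
        characteristic; estimates to 2 decimals, I² to 1."""
        buf = _io.StringIO()
        title = "Meta-epidemiological analysis: difference in SMD "
        title += "(high/unclear vs low risk of bias)"
        if self.robust:
            title += " — robust (CR2) sensitivity"
        buf.write(title + "\n")
        buf.write("=" * 86 + "\n")
        buf.write(
            f"{'Characteristic':<28}{'DMSD':>8}{'95% CI':>20}"
            f"{'I2 (%)':>9}{'MAs':>6}{'Arms':>7}\n"
        )
        buf.write("-" * 86 + "\n")
        for r in self.results:
            if r.skipped:
                buf.write(
                    f"{r.characteristic:<28}{'--':>8}{'--':>20}{'--':>9}"
                    f"{'--':>6}{'--':>7}  skipped: {r.skip_reason}\n"
                )
            else:
                ci = f"[{r.ci_low:.2f}, {r.ci_high:.2f}]"
                buf.write(
                    f"{r.characteristic:<28}{r.pooled_dmsd:>8.2f}{ci:>20}"
                    f"{r.i2:>9.1f}{r.n_mas:>6d}{r.n_arms:>7d}\n"
                )
        buf.write("=" * 86 + "\n")
        buf.write(
            "Positive DMSD: larger effect sizes in studies at high or "
            "unclear risk of bias.\n"
        )
        return buf.getvalue()

    def plot_forest(self, ax=None):
        """Forest plot of pooled DMSDs with 95% CIs, one row per
        evaluated characteristic."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        shown = [r for r in self.results if not r.skipped]
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.6 * max(len(shown), 1) + 1.5))
        ys = np.arange(len(shown))[::-1]
        for y, r in zip(ys, shown):
            ax.plot([r.ci_low, r.ci_high], [y, y], color="k", lw=1.2)
            ax.plot(r.pooled_dmsd, y, "s", color="k", ms=6)
        ax.axvline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(ys)
        ax.set_yticklabels(
            [f"{r.characteristic} (k={r.n_mas})" for r in shown]
        )
        ax.set_xlabel("Difference in SMD (high/unclear − low risk)")
        ax.figure.tight_layout()
        return ax
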