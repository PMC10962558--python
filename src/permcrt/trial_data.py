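"""Data model for multi-outcome cluster randomized trial observations.

The canonical container is long ("tidy") format: one row per individual
observation, with a cluster label, an optional integer time period, a binary
treatment indicator, covariate columns, and one column per outcome.  Treatment
is stored per row but is a cluster-period attribute: it must be constant
within each (cluster, period) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeSpec",
    "HypothesisSet",
    "ClusterTrialData",
    "ConfigError",
    "ValidationError",
    "read_trial_table",
    "write_trial_table",
]

FAMILIES = {"gaussian", "poisson", "bernoulli"}
LINKS = {"identity", "log", "logit"}
DEFAULT_LINK = {"gaussian": "identity", "poisson": "log", "bernoulli": "logit"}
SUPPORTED_FAMILY_LINKS = {
    ("gaussian", "identity"),
    ("poisson", "log"),
    ("bernoulli", "logit"),
}


class ConfigError(ValueError):
    """A configuration problem (missing column, bad family/link pair, ...)."""


class ValidationError(ValueError):
    """Input data violate a structural invariant of the trial design."""


@dataclass(frozen=True)
class OutcomeSpec:
    """Declaration of one outcome: its column, distribution family and link.

    ``covariate_terms`` names covariate columns entering the linear predictor;
    the special term ``"period"`` requests fixed effects for time periods 2..T.
    """

    name: str
    family: str
    link: str | None = None
    covariate_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}; choose from {sorted(FAMILIES)}")
        link = self.link if self.link is not None else DEFAULT_LINK[self.family]
        object.__setattr__(self, "link", link)
        if link not in LINKS:
            raise ConfigError(f"unknown link {link!r}; choose from {sorted(LINKS)}")
        if (self.family, link) not in SUPPORTED_FAMILY_LINKS:
            raise ConfigError(f"unsupported family-link pair ({self.family}, {link})")
        object.__setattr__(self, "covariate_terms", tuple(self.covariate_terms))


@dataclass(frozen=True)
class HypothesisSet:
    """The family of point null hypotheses H_j: delta_j = delta*_j.

    ``null_values`` is the vector delta* (one entry per analysed outcome),
    ``alpha`` the family-wise level, ``sidedness`` the alternative.
    """

    null_values: tuple[float, ...]
    alpha: float = 0.05
    sidedness: str = "two_sided"

    def __post_init__(self) -> None:
        object.__setattr__(self, "null_values", tuple(float(v) for v in self.null_values))
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.sidedness not in {"two_sided", "less", "greater"}:
            raise ConfigError(f"unknown sidedness {self.sidedness!r}")
        if not all(np.isfinite(self.null_values)):
            raise ConfigError("null_values must be finite")

    @property
    def n_hypotheses(self) -> int:
        return len(self.null_values)


@dataclass
class ClusterTrialData:
    """Validated long-format trial data plus derived index structures.

    Attributes
    ----------
    df : pandas.DataFrame
        One row per individual observation with normalized columns
        ``cluster``, ``period``, ``individual``, ``treatment`` plus covariate
        and outcome columns.
    outcome_names, covariate_names : tuple of str
        Which columns hold outcomes / covariates.
    """

    df: pd.DataFrame
    outcome_names: tuple[str, ...]
    covariate_names: tuple[str, ...] = ()

    # derived, filled in by validate()
    cluster_labels: np.ndarray = field(init=False, repr=False)
    cluster_codes: np.ndarray = field(init=False, repr=False)
    period_values: np.ndarray = field(init=False, repr=False)
    period_codes: np.ndarray = field(init=False, repr=False)
    treatment_matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.outcome_names = tuple(self.outcome_names)
        self.covariate_names = tuple(self.covariate_names)
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> "ClusterTrialData":
        """Check invariants and (re)build the derived index arrays.

        Idempotent: validating already-validated data changes nothing.
        """
        df = self.df
        required = ["cluster", "treatment", *self.outcome_names, *self.covariate_names]
        for col in required:
            if col not in df.columns:
                raise ConfigError(f"required column {col!r} not present in data")
        if "period" not in df.columns:
            df = df.assign(period=1)
        if "individual" not in df.columns:
            df = df.assign(individual=np.arange(len(df)))
        if len(df) == 0:
            raise ValidationError("data contain no rows")
        if len(self.outcome_names) < 1:
            raise ConfigError("at least one outcome column is required")

        checked = df[["treatment", *self.outcome_names, *self.covariate_names]]
        if checked.isna().any().any():
            bad = checked.columns[checked.isna().any()].tolist()
            raise ValidationError(f"missing values in columns {bad} after validation")

        treat = df["treatment"].to_numpy()
        if not np.isin(treat, [0, 1]).all():
            raise ValidationError("treatment indicator must be binary (0/1)")

        # treatment must be constant within each cluster-period
        g = df.groupby(["cluster", "period"], sort=True, observed=True)["treatment"]
        nun = g.nunique()
        if (nun > 1).any():
            cp = nun.index[nun > 1][0]
            raise ValidationError(
                f"treatment varies within cluster-period {cp}: D_ct must be constant"
            )

        self.df = df.reset_index(drop=True)
        self.cluster_labels, self.cluster_codes = np.unique(
            self.df["cluster"].to_numpy(), return_inverse=True
        )
        self.period_values, self.period_codes = np.unique(
            self.df["period"].to_numpy(), return_inverse=True
        )
        # D_ct as a (C, T) 0/1 matrix; -1 marks an empty cluster-period
        C, T = len(self.cluster_labels), len(self.period_values)
        D = np.full((C, T), -1.0)
        D[self.cluster_codes, self.period_codes] = self.df["treatment"].to_numpy(float)
        if (D < 0).any():
            c, t = np.argwhere(D < 0)[0]
            raise ValidationError(
                f"cluster {self.cluster_labels[c]!r} has no rows in period "
                f"{self.period_values[t]} (every cluster-period needs n_ct >= 1)"
            )
        self.treatment_matrix = D
        return self

    # -- convenience -------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)

    @property
    def n_periods(self) -> int:
        return len(self.period_values)

    @property
    def cluster_period_index(self) -> np.ndarray:
        """Flat (cluster, period) index per row, for fast grouped sums."""
        return self.cluster_codes * self.n_periods + self.period_codes

    @property
    def treatment(self) -> np.ndarray:
        return self.df["treatment"].to_numpy(float)

    @property
    def treated_clusters(self) -> np.ndarray:
        """Boolean arm membership per cluster (treated arm = any D_ct == 1)."""
        return (self.treatment_matrix == 1).any(axis=1)

    @property
    def arm_trajectories(self) -> tuple[np.ndarray, np.ndarray]:
        """(treated-arm, control-arm) treatment paths over periods.

        Requires every cluster in an arm to share one trajectory, which holds
        for parallel and baseline-rollout designs.
        """
        member = self.treated_clusters
        if not member.any() or member.all():
            raise ValidationError("both trial arms must be non-empty")
        treated = self.treatment_matrix[member]
        control = self.treatment_matrix[~member]
        if not (treated == treated[0]).all() or not (control == control[0]).all():
            raise ValidationError("clusters within an arm follow different treatment paths")
        return treated[0], control[0]

    def outcome(self, name: str) -> np.ndarray:
        if name not in self.outcome_names:
            raise ConfigError(f"{name!r} is not a declared outcome")
        return self.df[name].to_numpy(float)

    def check_outcome_family(self, spec: OutcomeSpec) -> None:
        """Verify outcome values conform to the declared family."""
        y = self.outcome(spec.name)
        if spec.family == "poisson":
            if (y < 0).any() or not np.allclose(y, np.round(y)):
                raise ValidationError(f"poisson outcome {spec.name!r} must be nonnegative integers")
        elif spec.family == "bernoulli":
            if not np.isin(y, [0.0, 1.0]).all():
                raise ValidationError(f"bernoulli outcome {spec.name!r} must be 0/1")


def read_trial_table(
    path,
    specs: list[OutcomeSpec],
    column_map: dict[str, str] | None = None,
    covariates: list[str] | None = None,
    sep: str | None = None,
    drop_missing: bool = False,
) -> ClusterTrialData:
    """Read a delimited trial table and return validated :class:`ClusterTrialData`.

    Parameters
    ----------
    column_map
        Maps canonical names (``cluster``, ``period``, ``individual``,
        ``treatment``) to the file's column names.  Unmapped canonical names
        are assumed to match literally.
    drop_missing
        If True, rows with missing values in mapped columns are dropped (the
        number dropped is reported via a printed note); default hard-fails.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    rename = {}
    for canonical in ("cluster", "period", "individual", "treatment"):
        src = column_map.get(canonical, canonical)
        if src in df.columns:
            rename[src] = canonical
        elif canonical in ("cluster", "treatment"):
            raise ConfigError(f"mapped column {src!r} for {canonical!r} not found in {path}")
    df = df.rename(columns=rename)

    covariates = list(covariates) if covariates is not None else sorted(
        {t for s in specs for t in s.covariate_terms if t != "period"}
    )
    for s in specs:
        if s.name not in df.columns:
            raise ConfigError(f"outcome column {s.name!r} not found in {path}")
    for c in covariates:
        if c not in df.columns:
            raise ConfigError(f"covariate column {c!r} not found in {path}")

    used = [c for c in df.columns if c in {"cluster", "period", "individual", "treatment"}]
    used += [s.name for s in specs] + covariates
    if drop_missing:
        n0 = len(df)
        df = df.dropna(subset=used)
        dropped = n0 - len(df)
        if dropped:
            print(f"note: dropped {dropped} rows with missing values")

    data = ClusterTrialData(
        df=df,
        outcome_names=tuple(s.name for s in specs),
        covariate_names=tuple(covariates),
    )
    for s in specs:
        data.check_outcome_family(s)
    return data


def write_trial_table(data: ClusterTrialData, path, sep: str = ",") -> None:
    """Write the long-format table back to delimited text (same dialect in/out)."""
    data.df.to_csv(path, sep=sep, index=False)
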