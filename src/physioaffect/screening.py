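"""Subject-variable screening: Pearson correlations with Bonferroni control.

Every psychophysiological feature, in every condition, is correlated across
subjects with each subject-specific variable (age plus the six trait scale
scores; gender is categorical and is handled by subgrouping, not here).
Significance is declared at the Bonferroni-corrected level
``family_alpha / n_variables`` — 0.05 over seven variables gives the
corrected threshold p < 0.007.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InsufficientDataError
from .features import FEATURE_NAMES
from .synth import SubjectProfile

#: The seven screened variables: age and the six trait scale scores.
DEFAULT_VARIABLES = (
    "age",
    "masculinity",
    "femininity",
    "extraversion",
    "neuroticism",
    "bis",
    "bas",
)


def bonferroni_alpha(family_alpha: float = 0.05, m: int = 1) -> float:
    """Per-test alpha controlling the family-wise error over m tests."""
    if m < 1:
        raise ConfigurationError(f"number of tests must be >= 1, got {m}")
    return family_alpha / m


def profiles_frame(profiles: list[SubjectProfile]) -> pd.DataFrame:
    """Tabulate subject profiles (one row per subject)."""
    return pd.DataFrame(
        [
            {
                "subject_id": p.subject_id,
                "age": p.age,
                "gender": p.gender,
                **{name: getattr(p, name) for name in SubjectProfile.TRAIT_FIELDS},
            }
            for p in profiles
        ]
    )


def screen_variables(
    matrix: pd.DataFrame,
    profiles,
    variables=DEFAULT_VARIABLES,
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate each (feature, condition) with each subject variable.

    Returns a table with one row per feature x condition x variable holding
    the Pearson r, the two-sided p-value (t-transform with n-2 df) and a
    significance flag at the Bonferroni-corrected alpha.
    """
    if isinstance(profiles, list):
        profiles = profiles_frame(profiles)
    unknown = [v for v in variables if v not in profiles.columns]
    if unknown:
        raise ConfigurationError(f"unknown screening variables: {unknown}")
    if "gender" in variables:
        raise ConfigurationError("gender is categorical; use subgrouping, not screening")

    merged = matrix.merge(profiles, on="subject_id", how="left", validate="many_to_one")
    alpha = bonferroni_alpha(family_alpha, len(variables))
    features = [c for c in FEATURE_NAMES if c in matrix.columns]
    rows = []
    for condition, sub in merged.groupby("condition", sort=False):
        if len(sub) < 4:
            raise InsufficientDataError(
                f"screening needs >= 4 subjects per condition, got {len(sub)} in {condition}"
            )
        for feature in features:
            for variable in variables:
                if np.std(sub[feature].to_numpy()) == 0 or np.std(sub[variable].to_numpy()) == 0:
                    # constant input: correlation undefined, never significant
                    r, p = float("nan"), float("nan")
                else:
                    r, p = stats.pearsonr(sub[feature], sub[variable])
                rows.append(
                    {
                        "feature": feature,
                        "condition": condition,
                        "variable": variable,
                        "r": float(r),
                        "p": float(p),
                        "significant": bool(p < alpha) if p == p else False,
                    }
                )
    table = pd.DataFrame(rows)
    table.attrs["corrected_alpha"] = alpha
    return table


def significant_only(table: pd.DataFrame) -> pd.DataFrame:
    """Filter to the significant rows, labelled feature_condition as in reports."""
    sig = table[table["significant"]].copy()
    sig.insert(0, "feature_condition", sig["feature"] + "_" + sig["condition"])
    return sig[["feature_condition", "variable", "r", "p"]].reset_index(drop=True)
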