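"""Multi-EC50 high-content profiles and cytostatic/cytotoxic dissection.

Each drug x cell-line pair collects the EC50s of all monitored parameters
(Area, Shape P2A, CellEvent, LysoTracker, ATP; up to two per parameter,
labeled with '-1' / '-2' increments for the lower and higher value).  A
"static" threshold — the highest tested concentration at which spheroid ATP
content shows no change from vehicle within the treatment window — splits
the profile: EC50s below the threshold reflect cytostatic (growth-arresting)
action, those above it cytotoxic (cell-killing) action.  The overall profile
is summarized as mostly cytostatic, a cytostatic-to-cytotoxic transition, or
purely cytotoxic.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doseresponse import (
    DoseResponseCurve,
    EC50Estimate,
    test_vs_control,
)
from .exceptions import ValidationError

#: phenotype parameters carried into the profile (3-D spheroid readouts)
PROFILE_PARAMETERS = ("Area", "P2A", "CE", "LysoT", "ATP")


@dataclass
class StaticThreshold:
    """Highest concentration with no detectable ATP change from vehicle."""

    drug: str
    cell_line: str
    value: float
    censored: str = "none"  # 'none' | 'above_max' | 'below_min'
    treatment_days: float = float("nan")
    basis_alpha: float = 0.05


@dataclass
class HCAProfile:
    drug: str
    cell_line: str
    ec50s: list = field(default_factory=list)
    threshold: StaticThreshold | None = None
    assignments: dict = field(default_factory=dict)  # label -> classification
    profile_class: str = ""
    unit: str = "nM"


def compute_static_threshold(
    atp_curve: DoseResponseCurve,
    alpha: float = 0.05,
    drug: str = "",
    cell_line: str = "",
    treatment_days: float = float("nan"),
    rule: str = "welch",
    equivalence_band: float = 0.10,
) -> StaticThreshold:
    """Static ATP threshold: the highest tested concentration c such that no
    concentration <= c differs significantly from vehicle at ``alpha``.

    The Welch p-values are Holm-adjusted across the tested concentrations:
    "no change observed" is a statement about the whole concentration
    series, and uncorrected per-concentration tests would declare a change
    somewhere on almost every flat 9-point curve.

    ``rule='equivalence'`` replaces the Welch test with a fixed band on the
    normalized mean (|mean - 1| < ``equivalence_band``).  All concentrations
    significant -> censored below the lowest; none significant -> censored
    above the highest.
    """
    concs = atp_curve.nonzero_concentrations
    if concs.size == 0:
        raise ValidationError("ATP curve has no nonzero concentrations")
    if rule == "welch":
        from .doseresponse import holm_adjust

        sig = holm_adjust(test_vs_control(atp_curve)).table.set_index(
            "concentration"
        )
        significant = {
            c: bool(sig.loc[c, "p_value"] < alpha)
            if np.isfinite(sig.loc[c, "p_value"])
            else False
            for c in concs
        }
    elif rule == "equivalence":
        significant = {
            c: abs(float(np.mean(atp_curve.responses[float(c)])) - 1.0)
            >= equivalence_band
            for c in concs
        }
    else:
        raise ValidationError(f"unknown threshold rule {rule!r}")

    threshold = None
    for i, c in enumerate(sorted(concs)):
        if significant[c]:
            if i == 0:
                return StaticThreshold(
                    drug, cell_line, float(sorted(concs)[0]),
                    censored="below_min", treatment_days=treatment_days,
                    basis_alpha=alpha,
                )
            threshold = float(sorted(concs)[i - 1])
            break
    if threshold is None:
        return StaticThreshold(
            drug, cell_line, float(max(concs)), censored="above_max",
            treatment_days=treatment_days, basis_alpha=alpha,
        )
    return StaticThreshold(
        drug, cell_line, threshold, treatment_days=treatment_days,
        basis_alpha=alpha,
    )


def _classify_one(ec50: EC50Estimate, threshold: StaticThreshold) -> str:
    """Cytostatic iff the EC50 is decidably below the threshold."""
    t = threshold.value
    if ec50.censored == "above_max":
        # true EC50 exceeds ec50.value; decidable only if the bound is
        # already at/above the threshold
        return "cytotoxic" if ec50.value >= t else "indeterminate"
    if ec50.censored == "below_min":
        return "cytostatic" if ec50.value <= t else "indeterminate"
    return "cytostatic" if ec50.value < t else "cytotoxic"


def classify_effects(
    ec50s: list[EC50Estimate],
    threshold: StaticThreshold,
    drug: str = "",
    cell_line: str = "",
    unit: str = "nM",
    cytostatic_fraction: float = 0.8,
) -> HCAProfile:
    """Label each EC50 and summarize the drug profile.

    ``mostly_cytostatic`` when at least ``cytostatic_fraction`` of decidable
    EC50s sit below the threshold, ``purely_cytotoxic`` when all sit above,
    otherwise a concentration-dependent ``transition``.
    """
    if not ec50s:
        raise ValidationError("at least one EC50 required")
    assignments = {e.label or str(i): _classify_one(e, threshold)
                   for i, e in enumerate(ec50s)}
    decided = [a for a in assignments.values() if a != "indeterminate"]
    if not decided:
        profile_class = "indeterminate"
    elif all(a == "cytotoxic" for a in decided):
        profile_class = "purely_cytotoxic"
    elif sum(a == "cytostatic" for a in decided) / len(decided) >= cytostatic_fraction:
        profile_class = "mostly_cytostatic"
    else:
        profile_class = "transition"
    return HCAProfile(
        drug=drug or threshold.drug,
        cell_line=cell_line or threshold.cell_line,
        ec50s=list(ec50s),
        threshold=threshold,
        assignments=assignments,
        profile_class=profile_class,
        unit=unit,
    )


def build_hca_table(profiles: list[HCAProfile]) -> pd.DataFrame:
    """Long-format table for the multi-EC50 profile diagram: one row per
    labeled EC50 with its assignment and the cell line's threshold."""
    rows = []
    for p in profiles:
        for e in p.ec50s:
            rows.append(
                {
                    "drug": p.drug,
                    "cell_line": p.cell_line,
                    "label": e.label,
                    "ec50": e.value,
                    "unit": p.unit,
                    "censored": e.censored,
                    "assignment": p.assignments.get(e.label, ""),
                    "profile_class": p.profile_class,
                    "threshold": p.threshold.value if p.threshold else np.nan,
                    "threshold_censored": (
                        p.threshold.censored if p.threshold else ""
                    ),
                }
            )
    columns = [
        "drug", "cell_line", "label", "ec50", "unit", "censored",
        "assignment", "profile_class", "threshold", "threshold_censored",
    ]
    return pd.DataFrame(rows, columns=columns)


def load_reference_ec50s() -> pd.DataFrame:
    """Published per-parameter EC50 fixture table (verbatim printed values,
    censored '>' entries flagged; 'n/a' cells absent)."""
    with importlib.resources.files("spherohca.data").joinpath(
        "tables3_4.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def profiles_from_reference(
    reference: pd.DataFrame | None = None,
    thresholds: dict | None = None,
    parameters=PROFILE_PARAMETERS,
) -> list[HCAProfile]:
    """Build profiles from the reference EC50 table.

    ``thresholds`` maps (drug, cell_line) to a :class:`StaticThreshold`;
    pairs without one get assignments left empty (thresholds are recomputed
    from data, never copied from the published figures).
    """
    if reference is None:
        reference = load_reference_ec50s()
    thresholds = thresholds or {}
    profiles = []
    for (drug, cell_line), grp in reference.groupby(["drug", "cell_line"]):
        grp = grp[grp.parameter.isin(parameters)]
        if grp.empty:
            continue
        ec50s = [
            EC50Estimate(
                value=float(r.value),
                label=f"{r.parameter}-{int(r.increment)}",
                censored=r.censored,
            )
            for r in grp.itertuples()
        ]
        thr = thresholds.get((drug, cell_line))
        if thr is not None:
            profiles.append(
                classify_effects(
                    ec50s, thr, drug=drug, cell_line=cell_line,
                    unit=str(grp.unit.iloc[0]),
                )
            )
        else:
            profiles.append(
                HCAProfile(drug=drug, cell_line=cell_line, ec50s=ec50s,
                           unit=str(grp.unit.iloc[0]))
            )
    return profiles


def plot_hca_profiles(profiles: list[HCAProfile], path=None):
    """Scatter of labeled EC50s per drug on a log concentration axis with
    per-cell-line static-threshold lines (the profile diagram)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = build_hca_table(profiles)
    drugs = sorted(table.drug.unique())
    fig, axes = plt.subplots(
        1, max(len(drugs), 1), figsize=(3 * max(len(drugs), 1), 4),
        squeeze=False,
    )
    colors = {"VCaP": "tab:green", "LNCaP": "tab:red"}
    for ax, drug in zip(axes[0], drugs):
        sub = table[table.drug == drug]
        labels = sorted(sub.label.unique())
        for i, lab in enumerate(labels):
            for _, r in sub[sub.label == lab].iterrows():
                ax.scatter(
                    i, r.ec50,
                    color=colors.get(r.cell_line, "gray"),
                    marker="^" if r.censored == "above_max" else "o",
                )
        for cl, sub_cl in sub.groupby("cell_line"):
            thr = sub_cl.threshold.iloc[0]
            if np.isfinite(thr):
                ax.axhline(thr, color=colors.get(cl, "gray"), ls="--", lw=1)
        ax.set_yscale("log")
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=90, fontsize=7)
        ax.set_title(drug, fontsize=9)
    axes[0][0].set_ylabel("EC50")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
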