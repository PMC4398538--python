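"""End-to-end orchestration: networks -> strengths -> models -> mediation.

This layer glues the per-subject operations into cohort-level analyses and
produces the long-format result tables the CLI writes out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import Atlas
from .metrics import PAIR_PRESETS, strength_table
from .netbuild import ConnectivityMatrix, functional_network, structural_network
from .preprocess import preprocess_panel
from .stats import AgeModel, MediationModel, ModelKind
from .synthetic import SyntheticCohort


def build_functional_networks(cohort: SyntheticCohort) -> list[ConnectivityMatrix]:
    """Preprocess every subject's panel and correlate it into a network."""
    if cohort.functional is None:
        raise ValueError("cohort was generated without functional data")
    nets = []
    for subj in cohort.functional:
        clean = preprocess_panel(subj.panel, subj.nuisance)
        nets.append(functional_network(clean))
    return nets


def build_structural_networks(cohort: SyntheticCohort) -> list[ConnectivityMatrix]:
    return [structural_network(t) for t in cohort.tallies]


def cohort_strength_table(
    networks, atlas: Atlas, pairs=None, preset: str | None = None
) -> pd.DataFrame:
    if pairs is None:
        pairs = PAIR_PRESETS[preset or "pfc_posterior"]
    return strength_table(networks, atlas, pairs)


def strengths_wide(strengths: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long strength table to one ``modality:unit_a:unit_b`` column per pair."""
    df = strengths.copy()
    df["key"] = df["modality"] + ":" + df["unit_a"] + ":" + df["unit_b"]
    wide = df.pivot_table(index="subject_id", columns="key", values="strength", sort=False)
    return wide.reset_index()


def fit_age_models(
    strengths: pd.DataFrame,
    cohort: pd.DataFrame,
    thickness: pd.DataFrame | None = None,
    alpha: float = 0.05,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Reduced, full and (when thickness is given) thickness-adjusted age
    models for every pair in a long strength table.

    Bonferroni correction is applied to the reduced-model age p-values within
    each modality family; the family size defaults to the number of pairs
    per modality (the table's row count), or can be fixed explicitly.

    Returns a long table with columns outcome, modality, model, coefficient,
    beta, se, t, p, p_bonferroni, significant.
    """
    rows = []
    fams: dict[str, list[int]] = {}
    for (modality, unit_a, unit_b), grp in strengths.groupby(
        ["modality", "unit_a", "unit_b"], sort=False
    ):
        merged = grp.merge(cohort, on="subject_id", validate="one_to_one")
        outcome = f"{unit_a}-{unit_b}"
        covs = {}
        if thickness is not None:
            th = merged[["subject_id"]].merge(thickness, on="subject_id")
            for lobe in dict.fromkeys((unit_a, unit_b)):  # keep order, drop dup
                if lobe in th.columns:
                    covs[f"thickness_{lobe}"] = th[lobe].to_numpy()
        fits = {
            ModelKind.REDUCED: AgeModel(
                merged["strength"], merged["age"], merged["sex"], outcome_name=outcome
            ).fit(ModelKind.REDUCED),
            ModelKind.FULL: AgeModel(
                merged["strength"], merged["age"], merged["sex"], outcome_name=outcome
            ).fit(ModelKind.FULL),
        }
        if covs:
            fits[ModelKind.THICKNESS_ADJUSTED] = AgeModel(
                merged["strength"],
                merged["age"],
                merged["sex"],
                covariates=covs,
                outcome_name=outcome,
            ).fit(ModelKind.THICKNESS_ADJUSTED)
        for kind, res in fits.items():
            for coef in res.params.index:
                if kind is ModelKind.REDUCED and coef == "age":
                    fams.setdefault(modality, []).append(len(rows))
                rows.append(
                    {
                        "outcome": outcome,
                        "modality": modality,
                        "model": kind.value,
                        "coefficient": coef,
                        "beta": float(res.params[coef]),
                        "se": float(res.bse[coef]),
                        "t": float(res.tvalues[coef]),
                        "p": float(res.pvalues[coef]),
                        "n": res.nobs,
                    }
                )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.nan
    out["significant"] = False
    for modality, idx in fams.items():
        p = out.loc[idx, "p"].to_numpy()
        m = family_size or p.size
        adj = np.minimum(1.0, m * p)
        out.loc[idx, "p_bonferroni"] = adj
        out.loc[idx, "significant"] = adj < alpha
    return out


@dataclass(frozen=True)
class MediationPathway:
    """Names one age -> mediator -> outcome test on strength/thickness columns."""

    mediator: str  # wide-table column, e.g. "structural:occipital:lateral_temporal"
    outcome: str
    label: str = ""


def run_mediation(
    wide: pd.DataFrame,
    cohort: pd.DataFrame,
    pathways: list[MediationPathway],
    thickness: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Sobel-Goodman tests for each named pathway.

    ``wide`` is the output of :func:`strengths_wide`; thickness mediators are
    addressed as ``thickness:<lobe>`` and resolved against the thickness
    table.
    """
    merged = wide.merge(cohort, on="subject_id", validate="one_to_one")
    if thickness is not None:
        th = thickness.rename(
            columns={c: f"thickness:{c}" for c in thickness.columns if c != "subject_id"}
        )
        merged = merged.merge(th, on="subject_id", validate="one_to_one")
    rows = []
    for pw in pathways:
        for col in (pw.mediator, pw.outcome):
            if col not in merged.columns:
                raise ValueError(f"pathway column {col!r} not found")
        res = MediationModel(
            merged["age"],
            merged[pw.mediator],
            merged[pw.outcome],
            merged["sex"],
            outcome_name=pw.outcome,
            mediator_name=pw.mediator,
        ).fit()
        rows.append(
            {
                "pathway": pw.label or f"age->{pw.mediator}->{pw.outcome}",
                "mediator": pw.mediator,
                "outcome": pw.outcome,
                "a": res.a,
                "se_a": res.se_a,
                "b": res.b,
                "se_b": res.se_b,
                "indirect": res.indirect,
                "z_sobel": res.z_sobel,
                "p_sobel": res.p_sobel,
                "z_aroian": res.z_aroian,
                "p_aroian": res.p_aroian,
                "z_goodman": res.z_goodman,
                "p_goodman": res.p_goodman,
                "total_beta_age": res.total.beta_age,
                "total_p_age": res.total.p_age,
                "direct_beta_age": res.direct.beta_age,
                "direct_p_age": res.direct.p_age,
                "classification": res.classify(alpha).value,
                "n": res.nobs,
            }
        )
    return pd.DataFrame(rows)
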