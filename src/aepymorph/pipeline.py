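"""Two-round taxon-delimitation pipeline.

Round 1 keeps specimens with less than 25% of their element's measurements
missing (strict: a bone at exactly 25% waits for round 2), imputes the
gaps by cross-validated iterative PCA, runs PCA on the unit-variance scaled
completed matrix, and introduces principal components stepwise into a
BIC-selected Gaussian-mixture model until the clustering stabilises.
Specimens whose classification uncertainty reaches 0.05 are removed.  If
another element resolved more clusters, a supervised re-fit at that fixed K
looks for subclusters.  Round 2 re-imputes an inclusive dataset (everything
left out of round 1, plus type specimens and localised specimens, plus the
round-1 members for context) and re-clusters at the K fixed by round 1.

ANOVA diagnostics per measurement and the per-cluster range tables feed the
taxonomic description of each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import Dataset, cluster_ranges_table
from .gmm import (
    FAMILIES,
    Assignment,
    SteppedResult,
    classify,
    pca,
    stepped_pc_selection,
)
from .impute import ImputationResult, fit_scaling, impute_iterative_pca, select_ncp_cv
from .scheme import Element
from .taxonomy import TaxonResolution, resolve_taxa

ROUND_FIRST = "first"
ROUND_SECOND = "second"


@dataclass(frozen=True)
class PipelineConfig:
    missing_gate: float = 0.25          # strict: round 1 requires fraction < gate
    uncertainty_threshold: float = 0.05  # inclusive: >= threshold is removed
    stability_delta: float = 2.0
    K_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    families: tuple[str, ...] = FAMILIES
    max_pcs: int = 6
    folds: int = 5
    impute_mode: str = "regularized"
    ncp_candidates: tuple[int, ...] | None = None
    log_transform: bool = False
    supervised_K: int | None = None      # None: use max K across elements
    seed: int = 0
    n_restarts: int = 3


@dataclass
class RoundResult:
    round: str
    specimen_ids: list[str]
    membership_reason: dict[str, list[str]]
    imputation: ImputationResult
    ncp: int
    cv_errors: dict[int, float]
    pca_result: object
    stepped: SteppedResult
    assignment: Assignment
    retained_ids: list[str]
    excluded_ids: list[str]


@dataclass
class ElementResult:
    element: Element
    round1: RoundResult
    round2: RoundResult | None
    supervised: tuple[SteppedResult, Assignment] | None
    labels: pd.DataFrame
    taxon_resolution: TaxonResolution | None
    cluster_ranges: pd.DataFrame | None = None

    @property
    def unsupervised_K(self) -> int:
        return self.round1.stepped.model.K

    @property
    def final_K(self) -> int:
        if self.supervised is not None:
            return self.supervised[0].model.K
        return self.unsupervised_K


@dataclass
class PipelineResult:
    elements: dict[Element, ElementResult]
    report: dict
    config: PipelineConfig

    def bundle(self, element: Element) -> dict:
        """Results bundle for :func:`aepymorph.datamodel.write_results`."""
        er = self.elements[element]
        return {
            "labels": er.labels,
            "report": self.report,
            "cluster_ranges": er.cluster_ranges,
        }


def _prepared_matrix(dataset_matrix: pd.DataFrame, log_transform: bool) -> pd.DataFrame:
    X = dataset_matrix.copy()
    if log_transform:
        X = np.log(X)
    # imputation needs every retained code observed at least twice with
    # spread; starved columns are dropped and reported
    counts = X.notna().sum()
    sds = X.std(ddof=1)
    keep = (counts >= 2) & (sds > 0)
    return X.loc[:, keep]


def _run_round(
    name: str,
    matrix: pd.DataFrame,
    reasons: dict[str, list[str]],
    config: PipelineConfig,
    seed: int,
    K_range,
) -> RoundResult:
    ncp, cv_errors = select_ncp_cv(
        matrix,
        candidates=list(config.ncp_candidates) if config.ncp_candidates else None,
        folds=config.folds, mode=config.impute_mode, seed=seed,
    )
    imp = impute_iterative_pca(matrix, ncp=ncp, mode=config.impute_mode)
    imp.cv_errors = cv_errors
    scaled = fit_scaling(imp.completed).transform(imp.completed)
    pca_result = pca(scaled)
    stepped = stepped_pc_selection(
        pca_result,
        K_range=K_range,
        families=config.families,
        max_pcs=config.max_pcs,
        stability_delta=config.stability_delta,
        seed=seed,
        n_restarts=config.n_restarts,
    )
    assignment = classify(
        stepped.model, pca_result.scores.iloc[:, : stepped.n_pcs_used]
    )
    excluded = assignment.uncertainty[
        assignment.uncertainty >= config.uncertainty_threshold
    ].index.tolist()
    retained = [s for s in matrix.index if s not in set(excluded)]
    return RoundResult(
        round=name,
        specimen_ids=list(matrix.index),
        membership_reason=reasons,
        imputation=imp,
        ncp=ncp,
        cv_errors=cv_errors,
        pca_result=pca_result,
        stepped=stepped,
        assignment=assignment,
        retained_ids=retained,
        excluded_ids=excluded,
    )


def run_element(
    dataset: Dataset, config: PipelineConfig, supervised_K: int | None = None
) -> ElementResult:
    """Run both rounds for one element.  ``supervised_K`` (if larger than
    the unsupervised K) triggers the fixed-K supervised re-fit."""
    mf = dataset.missing_fractions()
    round1_ids = mf.index[mf < config.missing_gate].tolist()
    if len(round1_ids) < 5:
        raise ValueError(
            f"{dataset.element.value}: only {len(round1_ids)} specimens pass "
            f"the {config.missing_gate:.0%} missingness gate; too few to cluster"
        )
    matrix_full = dataset.matrix()
    m1 = _prepared_matrix(matrix_full.loc[round1_ids], config.log_transform)
    r1 = _run_round(
        ROUND_FIRST, m1, {sid: ["under_gate"] for sid in round1_ids},
        config, config.seed, config.K_range,
    )

    supervised = None
    if supervised_K is not None and supervised_K > r1.stepped.model.K:
        sel = stepped_pc_selection(
            r1.pca_result,
            K_range=[supervised_K],
            families=config.families,
            max_pcs=config.max_pcs,
            stability_delta=config.stability_delta,
            seed=config.seed + 1,
            n_restarts=config.n_restarts,
        )
        sup_assignment = classify(
            sel.model, r1.pca_result.scores.iloc[:, : sel.n_pcs_used]
        )
        supervised = (sel, sup_assignment)

    # round 2: everything above the gate, everything dropped for
    # uncertainty, every type specimen and every localised specimen, plus
    # the round-1 members for a common reference frame
    reasons: dict[str, list[str]] = {}
    for r in dataset.records:
        why = []
        if mf[r.specimen_id] >= config.missing_gate:
            why.append("over_gate")
        if r.specimen_id in set(r1.excluded_ids):
            why.append("excluded_uncertainty_round1")
        if r.type_status is not None:
            why.append("type_specimen")
        if r.locality is not None:
            why.append("has_locality")
        if r.specimen_id in set(round1_ids):
            why.append("round1_member")
        reasons[r.specimen_id] = why
    round2_ids = [r.specimen_id for r in dataset.records]
    K2 = supervised[0].model.K if supervised is not None else r1.stepped.model.K
    round2 = None
    if len(round2_ids) > max(K2, 4):
        m2 = _prepared_matrix(matrix_full.loc[round2_ids], config.log_transform)
        round2 = _run_round(
            ROUND_SECOND, m2, reasons, config, config.seed + 2, [K2],
        )

    labels = _labels_table(dataset, r1, supervised, round2, config)
    resolution = _resolve(dataset, r1, supervised, config)
    return ElementResult(
        element=dataset.element,
        round1=r1,
        round2=round2,
        supervised=supervised,
        labels=labels,
        taxon_resolution=resolution,
    )


def _final_round1_assignment(r1, supervised) -> Assignment:
    return supervised[1] if supervised is not None else r1.assignment


def _resolve(dataset, r1, supervised, config) -> TaxonResolution | None:
    if not any(r.type_status is not None for r in dataset.records):
        return None
    assignment = _final_round1_assignment(r1, supervised)
    retained = [s for s in assignment.labels.index]
    sub = Assignment(
        responsibilities=assignment.responsibilities.loc[retained],
        labels=assignment.labels.loc[retained],
        uncertainty=assignment.uncertainty.loc[retained],
    )
    return resolve_taxa(sub, dataset.records, config.uncertainty_threshold)


def _labels_table(dataset, r1, supervised, round2, config) -> pd.DataFrame:
    rows = []
    for rnd, rr in ((ROUND_FIRST, r1), (ROUND_SECOND, round2)):
        if rr is None:
            continue
        for sid in rr.specimen_ids:
            excluded = sid in set(rr.excluded_ids)
            row = {
                "specimen_id": sid,
                "element": dataset.element.value,
                "round": rnd,
                "label": int(rr.assignment.labels.loc[sid]),
                "uncertainty": float(rr.assignment.uncertainty.loc[sid]),
                "status": "excluded_uncertainty" if excluded else "classified",
                "membership": ";".join(rr.membership_reason.get(sid, [])),
            }
            if rnd == ROUND_FIRST and supervised is not None:
                row["supervised_label"] = int(supervised[1].labels.loc[sid])
                row["supervised_uncertainty"] = float(
                    supervised[1].uncertainty.loc[sid]
                )
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    datasets: dict[Element, Dataset] | Dataset, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full two-round analysis over one or more elements.

    Unsupervised clustering runs per element first; the largest K found
    (or ``config.supervised_K``) is then imposed on elements that resolved
    fewer clusters, mirroring the cross-element supervised re-clustering of
    the published procedure.
    """
    if isinstance(datasets, Dataset):
        datasets = {datasets.element: datasets}
    config = config or PipelineConfig()

    # first pass: unsupervised K per element
    first_pass: dict[Element, ElementResult] = {}
    for element, ds in datasets.items():
        try:
            first_pass[element] = run_element(ds, config, supervised_K=None)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for element {Element(element).value!r}: {exc}"
            ) from exc

    K_target = config.supervised_K or max(
        er.unsupervised_K for er in first_pass.values()
    )

    results: dict[Element, ElementResult] = {}
    for element, ds in datasets.items():
        if first_pass[element].unsupervised_K < K_target:
            results[element] = run_element(ds, config, supervised_K=K_target)
        else:
            results[element] = first_pass[element]

    report = _build_report(datasets, results, config, K_target)
    return PipelineResult(elements=results, report=report, config=config)


def _build_report(datasets, results, config, K_target) -> dict:
    elements = {}
    for element, er in results.items():
        ds = datasets[element]
        r1 = er.round1
        retained_labels = r1.assignment.labels.loc[r1.retained_ids]
        final = _final_round1_assignment(r1, er.supervised)
        final_labels = final.labels.loc[
            [s for s in r1.retained_ids if s in final.labels.index]
        ]
        er.cluster_ranges = cluster_ranges_table(
            ds.subset(r1.retained_ids), final_labels
        )
        imputed_pct = float(r1.imputation.imputed_mask.to_numpy().mean() * 100)
        elements[Element(element).value] = {
            "n_specimens": len(ds),
            "n_round1": len(r1.specimen_ids),
            "n_round1_retained": len(r1.retained_ids),
            "n_round1_excluded_uncertainty": len(r1.excluded_ids),
            "round1_imputed_percent": imputed_pct,
            "ncp": r1.ncp,
            "cv_errors": {int(k): float(v) for k, v in r1.cv_errors.items()},
            "unsupervised_K": er.unsupervised_K,
            "final_K": er.final_K,
            "n_pcs_used": r1.stepped.n_pcs_used,
            "stable": bool(r1.stepped.stable),
            "bic_table": r1.stepped.selection.bic_table.to_dict(),
            "family": r1.stepped.model.family,
            "explained_fraction": [
                float(v) for v in r1.pca_result.explained_fraction[:4]
            ],
            "cluster_sizes": {
                int(k): int(v) for k, v in retained_labels.value_counts().items()
            },
            "n_round2": len(er.round2.specimen_ids) if er.round2 else 0,
            "round2_imputed_percent": (
                float(er.round2.imputation.imputed_mask.to_numpy().mean() * 100)
                if er.round2 else None
            ),
            "taxon_names": (
                {str(k): v for k, v in er.taxon_resolution.senior_names.items()}
                if er.taxon_resolution else None
            ),
        }
    return {
        "config": {
            "missing_gate": config.missing_gate,
            "uncertainty_threshold": config.uncertainty_threshold,
            "stability_delta": config.stability_delta,
            "K_range": list(config.K_range),
            "families": list(config.families),
            "impute_mode": config.impute_mode,
            "folds": config.folds,
            "log_transform": config.log_transform,
            "seed": config.seed,
            "supervised_K": K_target,
        },
        "elements": elements,
    }


def filter_uncertain(assignment: Assignment, threshold: float = 0.05) -> Assignment:
    """Drop specimens with classification uncertainty at or above the
    threshold.  Idempotent: filtering a filtered assignment removes nothing."""
    keep = assignment.uncertainty.index[assignment.uncertainty < threshold]
    return Assignment(
        responsibilities=assignment.responsibilities.loc[keep],
        labels=assignment.labels.loc[keep],
        uncertainty=assignment.uncertainty.loc[keep],
    )


def anova_diagnostics(
    matrix: pd.DataFrame,
    labels: pd.Series,
    base_alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA of each measurement across clusters.

    Only observed (non-imputed) values should be passed in ``matrix``
    (missing cells as NaN).  A code is testable when at least two clusters
    have at least two observations each; the Bonferroni threshold divides
    ``base_alpha`` by the number of codes actually tested.
    """
    common = matrix.index.intersection(labels.index)
    matrix = matrix.loc[common]
    labels = labels.loc[common]
    testable: dict[str, list[np.ndarray]] = {}
    skipped: dict[str, str] = {}
    for code in matrix.columns:
        groups = []
        for cluster in sorted(labels.dropna().unique(), key=str):
            vals = matrix.loc[labels == cluster, code].dropna().to_numpy()
            if len(vals) >= 2:
                groups.append(vals)
        if len(groups) >= 2:
            testable[code] = groups
        else:
            skipped[code] = "fewer than two clusters with two observations"
    m = len(testable)
    alpha = base_alpha / m if m else np.nan
    rows = []
    for code in matrix.columns:
        if code in testable:
            groups = testable[code]
            if all(np.var(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
                f_stat, p_val = 0.0, 1.0
            else:
                f_stat, p_val = sps.f_oneway(*groups)
            rows.append(
                {
                    "code": code,
                    "F": float(f_stat),
                    "p": float(p_val),
                    "n_groups": len(groups),
                    "alpha_bonferroni": alpha,
                    "significant": bool(p_val < alpha),
                    "skipped_reason": "",
                }
            )
        else:
            rows.append(
                {
                    "code": code, "F": np.nan, "p": np.nan, "n_groups": 0,
                    "alpha_bonferroni": alpha, "significant": False,
                    "skipped_reason": skipped[code],
                }
            )
    return pd.DataFrame(rows).set_index("code")


def round_spec(config: PipelineConfig | None = None) -> dict:
    """Human-readable description of the two inclusion rules."""
    config = config or PipelineConfig()
    return {
        ROUND_FIRST: f"missing_fraction < {config.missing_gate}",
        ROUND_SECOND: (
            "missing_fraction >= gate, or excluded for uncertainty in round 1, "
            "or type specimen, or has locality (round-1 members retained for "
            "a common reference frame)"
        ),
    }
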