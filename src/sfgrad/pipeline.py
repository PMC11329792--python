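"""End-to-end orchestration: synthetic or loaded data through every stage.

The canonical order is: aggregate subject streamline matrices and build the
13-measure SC stack; derive cosine FC from the activation matrix; select SC
predictors by exhaustive search over node-based cross-validation folds; map
parcel-wise SF correspondence; test per-term SF; build the macroscale
gradients and correlate each against the SF map with a permutation null;
and, when embeddings are available, run the term-level predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .functional import fc_from_activation
from .gradients import (
    GradientMap,
    activation_pca_first,
    axis_coordinate,
    correlate,
    diffusion_map,
    functional_diversity,
    lexical_gradient,
    thickness_map,
    top_terms,
)
from .predictors import nn_regress, svm_classify
from .regression import (
    build_pair_table,
    exhaustive_selection,
    node_folds,
    parcelwise_sf,
    region_zscores,
)
from .structural import build_sc_stack
from .synthetic import SyntheticDataset, _CATEGORIES
from .term_sf import TermSFConfig, results_to_frame, run_term_sf

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    stack: object
    fc: object
    selection: object
    sfmap: object
    region_summary: pd.DataFrame
    term_results: pd.DataFrame
    gradient_maps: dict = field(default_factory=dict)
    gradient_reports: dict = field(default_factory=dict)
    classifier: object = None
    regressor: object = None


def run_pipeline(
    ds: SyntheticDataset,
    k_folds: int = 10,
    seed: int = 0,
    n_perm: int = 10000,
    candidates=None,
    term_config: TermSFConfig | None = None,
    with_predictors: bool = True,
) -> PipelineResult:
    """Run every analysis stage on one dataset."""
    stack = build_sc_stack(ds.subject_counts, ds.subject_lengths, ds.atlas)
    fc = fc_from_activation(ds.activation)

    table = build_pair_table(stack, fc, candidates)
    folds = node_folds(ds.atlas, k_folds, seed=seed)
    selection = exhaustive_selection(table, folds=folds)
    sfmap = parcelwise_sf(stack, fc, selection.chosen_subset, ds.atlas)
    region_summary = region_zscores(sfmap, ds.atlas)

    term_results = results_to_frame(
        run_term_sf(ds.activation, stack["count"], term_config, ds.atlas)
    )

    # macroscale gradients
    profile = top_terms(ds.activation, k=10)
    emb = ds.embeddings.aligned(ds.activation.term_names)
    conc = ds.concreteness.reindex(ds.activation.term_names).to_numpy(float)
    maps = {
        "diffusion_1": GradientMap(diffusion_map(fc)[:, 0], "diffusion_1"),
        "activation_pc1": activation_pca_first(ds.activation),
        "functional_diversity": functional_diversity(profile, emb),
        "concreteness": lexical_gradient(profile, conc, "mean_score", "concreteness"),
    }
    cats = ds.categories.reindex(ds.activation.term_names)
    for cat in _CATEGORIES:
        member = (cats == cat).to_numpy(float)
        maps[f"category_{cat}"] = lexical_gradient(
            profile, member, "category_proportion", f"category_{cat}"
        )
    if ds.thickness is not None:
        maps["thickness"] = thickness_map([ds.thickness], ds.atlas)
    maps["axial"] = axis_coordinate(ds.atlas, "axial")

    reports = {}
    for name, gm in maps.items():
        try:
            reports[name] = correlate(gm, sfmap, n_perm=n_perm, seed=seed)
        except ValueError:
            reports[name] = None

    classifier = regressor = None
    if with_predictors:
        tf = term_results.set_index("term")
        hl = tf[tf["sf_class"].isin(["high", "low"])]
        if hl["sf_class"].nunique() == 2:
            idx = [ds.embeddings.terms.index(t) for t in hl.index]
            X = ds.embeddings.vectors[idx]
            classifier = svm_classify(X, hl["sf_class"].tolist(), seed=seed)
        tested = tf[np.isfinite(tf["fold_change"])]
        if len(tested) >= 20:
            idx = [ds.embeddings.terms.index(t) for t in tested.index]
            regressor = nn_regress(
                ds.embeddings.vectors[idx], tested["fold_change"].to_numpy(), seed=seed
            )

    return PipelineResult(
        stack=stack,
        fc=fc,
        selection=selection,
        sfmap=sfmap,
        region_summary=region_summary,
        term_results=term_results,
        gradient_maps=maps,
        gradient_reports=reports,
        classifier=classifier,
        regressor=regressor,
    )
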