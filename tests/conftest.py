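"""Shared fixtures: small fast synthetic studies for unit tests and the
full-scale built-in study (48 runs) shared by the slower end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from vinomix import synthio
from vinomix.synthio import CompoundSpec, SampleMeta, StudyRecipe

SMALL_LADDER = {7: 2.0, 8: 3.5, 9: 5.0, 10: 6.5, 11: 8.0, 12: 9.5}


def small_compound(
    name: str = "X",
    ri: float = 1000.0,
    base: float = 100.0,
    cv: float = 0.0,
    mult: dict | None = None,
    spectrum=((43, 999), (71, 500), (99, 250)),
    threshold: float | None = None,
) -> CompoundSpec:
    return CompoundSpec(
        name=name,
        spectrum=spectrum,
        true_ri=ri,
        base_conc=base,
        effect_multiplier=mult or {},
        cv=cv,
        odor_threshold=threshold,
    )


def small_design(n_vines: int = 1, injections: int = 1, rootstocks=("Own", "1103P"), irrigations=("Full",)):
    out = []
    for rs in rootstocks:
        for irr in irrigations:
            for v in range(1, n_vines + 1):
                for inj in range(1, injections + 1):
                    out.append(SampleMeta(f"{rs}_{irr}_v{v}", rs, irr, 2018, v, inj))
    return out


def small_recipe(compounds=None, design=None, seed: int = 0, **kw) -> StudyRecipe:
    defaults = dict(
        ladder=SMALL_LADDER,
        internal_standards=[("2-Octanol", 50.0)],
        rt_drift_sd=0.0,
        noise_floor=0.0,
        scan_hz=120.0,
        rt_range=(1.0, 11.0),
        seed=seed,
    )
    defaults.update(kw)
    return StudyRecipe(
        design=design or small_design(),
        compounds=compounds or [small_compound()],
        **defaults,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def planted_pipeline(tmp_path_factory):
    """Full built-in planted study (48 runs) through the whole funnel.

    Shared across end-to-end tests; permutation count reduced to keep the
    suite fast (the permutation estimator itself is unit-tested separately).
    """
    from vinomix.pipeline import PipelineConfig, StatsParams, run_pipeline

    outdir = tmp_path_factory.mktemp("planted")
    cfg = PipelineConfig(seed=1, stats=StatsParams(permutations=200))
    manifest = run_pipeline(cfg, outdir)
    recipe = synthio.default_study_recipe(seed=1)
    return {"outdir": outdir, "manifest": manifest, "recipe": recipe, "config": cfg}


@pytest.fixture(scope="session")
def null_feature_stats():
    """Null study (no planted effects): processed feature matrix plus the
    per-feature rootstock ANOVA results."""
    from vinomix import diffstats, features
    from vinomix.identify import AlkaneLadder
    from vinomix.pipeline import _is_feature

    recipe = synthio.default_study_recipe(seed=7, planted=False)
    runs, truth = synthio.simulate_study(recipe)
    peaks = []
    for run in runs:
        peaks.extend(features.detect_peaks(run))
    warps, corrected, _ = features.correct_rt(peaks, n_runs=len(runs))
    feats = features.group_peaks(corrected, recipe.design)
    feats = features.fill_missing(feats, runs, warps)
    feats = features.average_technical_replicates(feats, recipe.design)
    table = features.features_to_dataframe(feats)
    bio = {m.sample_id: m for m in recipe.design}
    is_feat = _is_feature(feats, AlkaneLadder.from_mapping(recipe.ladder), "2-Octanol")
    processed = diffstats.preprocess(
        diffstats.FeatureMatrix(values=table.T, meta=bio, state="raw"), is_feat.feature_id
    )
    results = diffstats.anova_per_feature(processed, "rootstock")
    return {"recipe": recipe, "features": feats, "matrix": processed, "results": results}
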