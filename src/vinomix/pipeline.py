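"""End-to-end orchestration of the untargeted→targeted funnel.

detect → align → group/fill → average replicates → preprocess → per-factor
ANOVA/FDR → PCA + PLS-DA + variance partition → pseudo-spectra → two-step
identification → standard confirmation → calibration/quantitation → OAV
ranking → compound-level two-way ANOVA. Every intermediate table is written
as CSV next to a JSON manifest carrying versions, parameters, the seed and
the funnel counts (n_features → n_significant → n_tentative → n_confirmed →
n_quantified, strictly non-increasing).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diffstats, features, identify, quantify, synthio
from .features import DetectionParams, GroupingParams
from .identify import AlkaneLadder
from .synthio import LibrarySpectrum, Run, SampleMeta, StudyRecipe

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StatsParams", "IdentifyParams", "QuantifyParams", "run_pipeline", "run_study"]


@dataclass(frozen=True)
class StatsParams:
    alpha: float = 0.05
    fdr: str = "bh"
    pcs: int = 20
    plsda_components: int = 2
    permutations: int = 1000
    top_k: int = 25


@dataclass(frozen=True)
class IdentifyParams:
    min_match: int = 700
    ri_tol: float = 15.0
    pseudospec_gap_s: float = 3.0


@dataclass(frozen=True)
class QuantifyParams:
    is_name: str = "2-Octanol"
    is_conc: float = 50.0
    min_r2: float = 0.99
    posthoc: str = "tukey"
    confirm_rt_tol_s: float = 3.0


@dataclass
class PipelineConfig:
    """Serializable configuration of a full pipeline run.

    With ``synthetic=True`` the built-in study is simulated (``seed``,
    ``planted`` and ``cv`` control it); otherwise ``runs_dir`` (mzML),
    ``metadata``, ``library`` (MSP), ``ladder`` (CSV), ``calibration`` and
    ``thresholds`` paths must resolve.
    """

    synthetic: bool = True
    planted: bool = True
    cv: float = 0.15
    runs_dir: str | None = None
    metadata: str | None = None
    library: str | None = None
    ladder: str | None = None
    calibration: str | None = None
    thresholds: str | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    grouping: GroupingParams = field(default_factory=GroupingParams)
    stats: StatsParams = field(default_factory=StatsParams)
    identify: IdentifyParams = field(default_factory=IdentifyParams)
    quantify: QuantifyParams = field(default_factory=QuantifyParams)
    fill: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(doc)
        for key, typ in (
            ("detection", DetectionParams),
            ("grouping", GroupingParams),
            ("stats", StatsParams),
            ("identify", IdentifyParams),
            ("quantify", QuantifyParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_known = {f.name for f in dataclasses.fields(typ)}
                sub_unknown = set(kwargs[key]) - sub_known
                if sub_unknown:
                    raise ValueError(f"unknown {key} keys: {sorted(sub_unknown)}")
                kwargs[key] = typ(**kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Resolve inputs (simulate or load), run the full funnel, write the
    report bundle into ``outdir`` and return the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.synthetic:
        recipe = synthio.default_study_recipe(seed=config.seed, planted=config.planted, cv=config.cv)
        runs, truth = synthio.simulate_study(recipe)
        metadata = recipe.design
        library = synthio.default_library()
        ladder = AlkaneLadder.from_mapping(recipe.ladder)
        thresholds = synthio.default_thresholds()
        named = [c for c in recipe.compounds if not c.name.startswith("Unknown_")]
        cal_runs, cal_levels = synthio.simulate_calibration_runs(recipe, named)
        truth.to_csv(outdir / "truth.csv")
        synthio.write_metadata(metadata, outdir / "metadata.csv")
    else:
        if not (config.runs_dir and config.metadata and config.library and config.ladder):
            raise ValueError("non-synthetic runs require runs_dir, metadata, library and ladder paths")
        metadata = synthio.read_metadata(config.metadata)
        paths = sorted(Path(config.runs_dir).glob("*.mzML"))
        runs = synthio.read_runs(paths, metadata)
        library = synthio.read_library(config.library)
        ladder = AlkaneLadder.from_csv(config.ladder)
        thresholds = pd.read_csv(config.thresholds) if config.thresholds else pd.DataFrame(columns=["compound", "threshold_ugL"])
        cal_runs, cal_levels = [], pd.DataFrame(columns=["compound", "level", "run_id", "conc_ugL"])
        if config.calibration:
            cal_levels = pd.read_csv(config.calibration)
        truth = None
    return run_study(
        runs=runs,
        metadata=metadata,
        library=library,
        ladder=ladder,
        thresholds=thresholds,
        config=config,
        outdir=outdir,
        calibration_runs=cal_runs,
        calibration_levels=cal_levels,
    )


def _is_feature(feats: Sequence[features.Feature], ladder: AlkaneLadder, is_name: str, tol_s: float = 9.0):
    """Locate the internal-standard quantifier feature by expected RI and base ion."""
    spec = synthio.INTERNAL_STANDARDS[is_name]
    expected_rt = synthio.ri_to_rt(spec.true_ri, dict(ladder.entries))
    base_mz = max(spec.spectrum, key=lambda p: p[1])[0]
    cands = [f for f in feats if f.mzmed == base_mz and abs(f.rtmed - expected_rt) * 60.0 <= tol_s]
    if not cands:
        raise ValueError(f"internal standard {is_name!r} feature (m/z {base_mz}) not found near {expected_rt:.2f} min")
    return max(cands, key=lambda f: float(np.mean(list(f.intensity.values()))))


def _compound_quantifier_peak(run: Run, mz: int, expected_rt: float, params: DetectionParams, tol_s: float = 9.0):
    peaks = [p for p in features.detect_peaks(run, params) if p.mz == mz and abs(p.rt - expected_rt) * 60.0 <= tol_s]
    if not peaks:
        return None
    return max(peaks, key=lambda p: p.area)


def run_study(
    runs: Sequence[Run],
    metadata: Sequence[SampleMeta],
    library: Sequence[LibrarySpectrum],
    ladder: AlkaneLadder,
    thresholds: pd.DataFrame,
    config: PipelineConfig,
    outdir: str | Path,
    calibration_runs: Sequence[Run] = (),
    calibration_levels: pd.DataFrame | None = None,
) -> dict:
    """Run the funnel on in-memory inputs and write the report bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "params": {
            "detection": dataclasses.asdict(config.detection),
            "grouping": dataclasses.asdict(config.grouping),
            "stats": dataclasses.asdict(config.stats),
            "identify": dataclasses.asdict(config.identify),
            "quantify": dataclasses.asdict(config.quantify),
        },
        "counts": {},
    }
    counts = manifest["counts"]
    stage = "detect"
    try:
        # --- detection ----------------------------------------------------
        all_peaks: list[features.Peak] = []
        for run in runs:
            all_peaks.extend(features.detect_peaks(run, config.detection))
        counts["n_runs"] = len(runs)
        counts["n_peaks"] = len(all_peaks)
        logger.info("detect: %d peaks across %d runs", len(all_peaks), len(runs))
        _write_csv(features.peaks_to_dataframe(all_peaks), outdir / "peaks.csv")

        # --- alignment ----------------------------------------------------
        stage = "align"
        warps, corrected, warp_diag = features.correct_rt(all_peaks, n_runs=len(runs))
        _write_csv(warp_diag, outdir / "warp_diagnostics.csv")
        feats = features.group_peaks(corrected, metadata, config.grouping)
        if config.fill:
            feats = features.fill_missing(feats, runs, warps)
        _write_csv(
            features.features_to_dataframe(feats), outdir / "feature_table_runs.csv", index=True
        )
        feats = features.average_technical_replicates(feats, metadata)
        table = features.features_to_dataframe(feats)
        _write_csv(table, outdir / "feature_table.csv", index=True)
        counts["n_features"] = len(feats)
        logger.info("align: %d features", len(feats))

        # --- statistics ---------------------------------------------------
        stage = "stats"
        bio_meta: dict[str, SampleMeta] = {}
        for m in metadata:
            bio_meta.setdefault(m.sample_id, m)
        matrix = diffstats.FeatureMatrix(values=table.T, meta=bio_meta, state="raw")
        is_feat = _is_feature(feats, ladder, config.quantify.is_name)
        processed = diffstats.preprocess(matrix, is_feat.feature_id)
        counts["n_features_tested"] = processed.n_features

        significant: set[str] = set()
        uni = {}
        for factor in ("rootstock", "irrigation"):
            res = diffstats.anova_per_feature(processed, factor)
            uni[factor] = res
            _write_csv(res, outdir / f"univariate_{factor}.csv")
            sig = set(res.loc[res["q"] <= config.stats.alpha, "feature_id"])
            significant |= sig
            counts[f"n_significant_{factor}"] = len(sig)
            _write_csv(
                diffstats.top_k_table(processed, res, config.stats.top_k),
                outdir / f"top{config.stats.top_k}_{factor}.csv",
                index=True,
            )
        counts["n_significant"] = len(significant)
        pd.Series(sorted(significant), name="feature_id").to_csv(outdir / "significant_features.csv", index=False)
        logger.info("stats: %d significant features", len(significant))

        model_matrix = processed.restrict(sorted(significant)) if len(significant) >= 2 else processed
        if len(significant) < 2:
            logger.info("fewer than 2 significant features; multivariate models use all features")
        k = min(config.stats.pcs, model_matrix.n_samples - 1, model_matrix.n_features)
        pca = diffstats.pca_fit(model_matrix, k)
        _write_csv(pca.scores, outdir / "pca_scores.csv", index=True)
        _write_csv(pca.loadings, outdir / "pca_loadings.csv", index=True)
        _write_csv(
            pd.DataFrame({"pc": np.arange(1, k + 1), "var_fraction": pca.var_fraction}),
            outdir / "pca_variance.csv",
        )
        _write_csv(diffstats.variance_partition(pca, bio_meta), outdir / "variance_partition.csv")

        plsda_summary = {}
        rng = np.random.default_rng(config.seed + 1)
        for factor in ("rootstock", "irrigation"):
            model = diffstats.plsda_fit(model_matrix, factor, config.stats.plsda_components)
            perm_p, _, _ = diffstats.permutation_test(
                model_matrix, factor, config.stats.plsda_components, B=config.stats.permutations, rng=rng
            )
            model.perm_p, model.B = perm_p, config.stats.permutations
            plsda_summary[factor] = {
                "R2Y": model.R2Y,
                "Q2": model.Q2,
                "perm_p": perm_p,
                "B": config.stats.permutations,
                "n_components": model.n_components,
                "n_vip_gt_1": int((model.vip > 1).sum()),
            }
            model.vip.to_csv(outdir / f"vip_{factor}.csv")
        (outdir / "plsda.json").write_text(json.dumps(plsda_summary, sort_keys=True, indent=1))

        # --- identification -----------------------------------------------
        stage = "identify"
        sig_feats = [f for f in feats if f.feature_id in significant]
        pseudo = identify.build_pseudospectra(sig_feats, config.identify.pseudospec_gap_s)
        counts["n_pseudospectra"] = len(pseudo)
        hits = identify.two_step_confirm(
            pseudo, library, ladder, config.identify.min_match, config.identify.ri_tol
        )
        counts["n_tentative"] = len({h.compound for h in hits if h.status == "tentative"})
        counts["n_orphans"] = sum(1 for h in hits if h.status == "orphan")

        # --- confirmation + quantitation ----------------------------------
        stage = "quantify"
        lib_by_name = {e.name: e for e in library}
        cal_levels = calibration_levels if calibration_levels is not None else pd.DataFrame()
        standard_run = None
        if len(calibration_runs):
            # the top calibration level doubles as the authentic-standard run
            standard_run = calibration_runs[-1]
        confirmed: list[identify.IdentificationHit] = []
        for h in hits:
            if h.status != "tentative":
                continue
            if standard_run is None:
                continue
            status = identify.confirm_with_standard(
                h,
                standard_run,
                rt_tolerance_s=config.quantify.confirm_rt_tol_s,
                min_match=config.identify.min_match,
                gap_s=config.identify.pseudospec_gap_s,
                detection_params=config.detection,
            )
            if status == "confirmed":
                h.status = "confirmed"
                confirmed.append(h)
        counts["n_confirmed"] = len({h.compound for h in confirmed})
        _write_csv(identify.hits_to_dataframe(hits), outdir / "hits.csv")

        # calibration curves from the calibration-series runs
        curves: dict[str, quantify.CalibrationCurve] = {}
        if len(calibration_runs) and len(cal_levels):
            run_by_id = {r.meta.run_id: r for r in calibration_runs}
            is_spec = synthio.INTERNAL_STANDARDS[config.quantify.is_name]
            is_rt = synthio.ri_to_rt(is_spec.true_ri, dict(ladder.entries))
            is_mz = max(is_spec.spectrum, key=lambda p: p[1])[0]
            cal_peak_cache: dict[tuple[str, int, float], object] = {}

            def _area(run_id: str, mz: int, rt: float) -> float | None:
                key = (run_id, mz, round(rt, 3))
                if key not in cal_peak_cache:
                    cal_peak_cache[key] = _compound_quantifier_peak(run_by_id[run_id], mz, rt, config.detection)
                pk = cal_peak_cache[key]
                return None if pk is None else pk.area

            for compound, sub in cal_levels.groupby("compound"):
                entry = lib_by_name.get(compound)
                if entry is None or entry.ri_lit is None:
                    continue
                base_mz = int(entry.mz[np.argmax(entry.intensity)])
                try:
                    exp_rt = synthio.ri_to_rt(entry.ri_lit, dict(ladder.entries))
                except ValueError:
                    continue
                pts = []
                for row in sub.itertuples():
                    a = _area(row.run_id, base_mz, exp_rt)
                    b = _area(row.run_id, is_mz, is_rt)
                    if a is not None and b is not None and b > 0:
                        pts.append((float(row.conc_ugL), a / b))
                if len(pts) >= 2:
                    curves[compound] = quantify.fit_calibration(
                        pts, compound, config.quantify.is_name, config.quantify.min_r2
                    )
            _write_csv(
                pd.DataFrame(
                    [
                        {
                            "compound": c.compound,
                            "slope": c.slope,
                            "intercept": c.intercept,
                            "r2": c.r2,
                            "x_min": c.x_min,
                            "x_max": c.x_max,
                            "n_levels": c.n_levels,
                            "usable": c.usable,
                        }
                        for c in curves.values()
                    ]
                ),
                outdir / "calibration_curves.csv",
            )

        thr_by_compound = (
            dict(zip(thresholds["compound"], thresholds["threshold_ugL"])) if len(thresholds) else {}
        )
        feat_by_id = {f.feature_id: f for f in feats}
        is_by_sample = {sid: v for sid, v in is_feat.intensity.items()}
        quants: list[quantify.Quantitation] = []
        quantified_compounds: set[str] = set()
        seen_compounds: set[str] = set()
        for h in sorted(
            (h for h in hits if h.status in ("confirmed", "tentative") and h.compound),
            key=lambda h: (h.status != "confirmed", -h.match_factor),
        ):
            if h.compound in seen_compounds:
                continue
            seen_compounds.add(h.compound)
            entry = lib_by_name[h.compound]
            base_mz = int(entry.mz[np.argmax(entry.intensity)])
            members = [feat_by_id[fid] for fid in h.pseudo_spectrum.member_features]
            quant_feats = [f for f in members if f.mzmed == base_mz] or members
            qf = max(quant_feats, key=lambda f: float(np.mean(list(f.intensity.values()))))
            curve = curves.get(h.compound)
            use_curve = h.status == "confirmed" and curve is not None and curve.usable
            for sid in sorted(qf.intensity):
                if sid not in is_by_sample:
                    continue
                ratio = quantify.response_ratio(qf.intensity[sid], is_by_sample[sid])
                if use_curve:
                    conc, flags = quantify.predict_concentration(curve, ratio)
                    mode = "quantified"
                else:
                    conc, flags, mode = quantify.semi_quantify(ratio, config.quantify.is_conc), set(), "semi"
                oav = quantify.compute_oav(conc, thr_by_compound.get(h.compound))
                quants.append(quantify.Quantitation(h.compound, sid, conc, mode, oav, flags))
            if use_curve:
                quantified_compounds.add(h.compound)
        counts["n_quantified"] = len(quantified_compounds)
        qdf = pd.DataFrame(
            [
                {
                    "compound": q.compound,
                    "sample_id": q.sample_id,
                    "conc_ugL": q.conc,
                    "mode": q.mode,
                    "oav": q.oav,
                    "flags": ";".join(sorted(q.flags)),
                }
                for q in quants
            ]
        )
        _write_csv(qdf, outdir / "quantitation.csv")

        # OAV ranking (mean concentration per compound)
        if len(qdf):
            rank = (
                qdf.groupby(["compound", "mode"], as_index=False)
                .agg(mean_conc_ugL=("conc_ugL", "mean"), mean_oav=("oav", "mean"))
                .sort_values(["mean_oav", "compound"], ascending=[False, True], na_position="last")
            )
        else:
            rank = pd.DataFrame(columns=["compound", "mode", "mean_conc_ugL", "mean_oav"])
        _write_csv(rank, outdir / "oav_ranking.csv")

        # compound-level two-way ANOVA with letters
        anova_rows = []
        for compound in sorted(quantified_compounds):
            sub = qdf[qdf["compound"] == compound].set_index("sample_id")["conc_ugL"]
            res = quantify.compound_anova(
                sub, bio_meta, compound, config.stats.alpha, config.quantify.posthoc
            )
            row = {
                "compound": compound,
                "p_rootstock": res.p_rootstock,
                "p_irrigation": res.p_irrigation,
                "p_interaction": res.p_interaction,
            }
            for label, letter in sorted(res.letters.items()):
                if isinstance(label, tuple):
                    rs, irr = label
                    row[f"{rs}/{irr}"] = f"{res.cell_means.loc[rs, irr]:.3g} {letter}"
                else:
                    row[str(label)] = f"{res.cell_means.loc[label].mean():.3g} {letter}"
            anova_rows.append(row)
        _write_csv(pd.DataFrame(anova_rows), outdir / "compound_anova.csv")
    except Exception as exc:  # noqa: BLE001 - annotate failing stage, keep partial outputs
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    funnel = [
        counts.get("n_features", 0),
        counts.get("n_significant", 0),
        counts.get("n_tentative", 0),
        counts.get("n_confirmed", 0),
        counts.get("n_quantified", 0),
    ]
    manifest["funnel"] = funnel
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
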