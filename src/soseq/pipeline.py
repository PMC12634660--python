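"""End-to-end orchestration: run every analysis stage on a dataset
directory and write the result bundle.

Stage order follows the data dependencies: usage statistics (and the DM
set) first, then trajectory shapes, transition networks, contact-aligned
composition, syntax dynamics, parametric classes and finally the PCA
summaries.  A failed stage aborts the run with the stage name; outputs
written so far are preserved and the manifest records the failure.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_core import AnalysisConfig, Dataset, load_dataset
from . import composition, kinematics, network, pca, syllables, syntax, trajectories

logger = logging.getLogger("soseq")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_all(
    data: str | Path | Dataset,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> dict:
    """Run the full analysis and write CSV/JSON/GraphML outputs.

    Returns the summary dictionary that is also written to
    ``summary.json``.
    """
    t_start = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(data, Dataset):
        dataset = data
        data_path = None
    else:
        data_path = Path(data)
        dataset = load_dataset(data_path, config)
    cfg = config or dataset.config
    summary: dict = {"seed": seed, "alpha": cfg.alpha}
    manifest: dict = {
        "soseq_version": __version__,
        "config": cfg.to_dict(),
        "seed": seed,
        "data_dir": str(data_path) if data_path else "<in-memory>",
        "stages": {},
        "warnings": [],
    }
    has_annotations = any(
        r.annotations for r in dataset.by_context("dyadic")
    )
    has_tracks = all(r.tracks for r in dataset.recordings)

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - recorded then re-raised
                manifest["stages"][name] = {
                    "status": "failed",
                    "error": str(exc),
                }
                _write_manifest(out_dir, manifest, failed=name)
                raise StageFailure(name, exc) from exc
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.time() - t0, 3),
            }
        return wrap

    state: dict = {}

    @stage("syllables")
    def _syllables():
        table = syllables.build_proportion_table(dataset)
        retained, mapping = syllables.filter_syllables(
            table.pooled_onset(), cfg.onset_threshold
        )
        comparison = syllables.compare_contexts(table, cfg.alpha)
        state.update(table=table, retained=retained, comparison=comparison)
        table.onset.to_csv(out_dir / "proportions_onset.csv")
        table.frame.to_csv(out_dir / "proportions_frame.csv")
        pd.DataFrame(
            [
                {
                    "syllable": r.name,
                    "statistic": r.statistic,
                    "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                    "significant": r.significant,
                }
                for r in comparison.results
            ]
        ).to_csv(out_dir / "dm_tests.csv", index=False)
        if has_tracks:
            dist = {
                ctx: [
                    syllables.distance_moved(t)
                    for r in dataset.by_context(ctx)
                    for t in r.tracks.values()
                ]
                for ctx in ("solitary", "dyadic")
            }
            from scipy.stats import mannwhitneyu

            mw = mannwhitneyu(
                dist["solitary"], dist["dyadic"], alternative="two-sided"
            )
            summary["distance_moved_mm"] = {
                k: float(np.mean(v)) for k, v in dist.items()
            }
            summary["distance_moved_p"] = float(mw.pvalue)
        summary["n_retained_syllables"] = len(retained)
        summary["dm_syllables"] = comparison.dm
        summary["n_dm"] = len(comparison.dm)
        if has_annotations:
            assoc = syllables.contact_association(
                dataset, comparison.dm or retained, "active", cfg.alpha
            )
            pd.DataFrame(
                [
                    {
                        "syllable": r.name,
                        "chi2": r.statistic,
                        "p_raw": r.p_raw,
                        "p_adjusted": r.p_adjusted,
                        "significant": r.significant,
                    }
                    for r in assoc["tests"]
                ]
            ).to_csv(out_dir / "contact_tests.csv", index=False)
            summary["contact_associated"] = assoc["significant"]
        if has_tracks and dataset.by_context("dyadic"):
            quart = syllables.quartile_association(
                dataset, comparison.dm or retained, cfg.alpha
            )
            quart["proportions"].to_csv(out_dir / "quartile_table.csv")
            summary["imd_quartiles_mm"] = [
                round(float(v), 1) for v in quart["quartile_values"]
            ]

    @stage("trajectories")
    def _trajectories():
        if not has_tracks:
            manifest["warnings"].append("no tracks: trajectory stage skipped")
            return
        comparison = state["comparison"]
        instances: dict[int, list] = {}
        for rec in dataset.recordings:
            for aid, seq in rec.sequences.items():
                if aid not in rec.tracks:
                    continue
                bouts = syllables.extract_bouts(seq)
                by_syll: dict[int, list] = {}
                for b in bouts:
                    by_syll.setdefault(b.syllable, []).append(b)
                for s, bs in by_syll.items():
                    instances.setdefault(s, []).extend(
                        trajectories.egocentric_instances(bs, rec.tracks[aid])
                    )
        trajs = [
            trajectories.egocentric_mean_trajectory(s, [], paths)
            for s, paths in sorted(instances.items())
            if paths
        ]
        state["trajectories"] = trajs
        dist, link, newick = trajectories.similarity_dendrogram(trajs)
        (out_dir / "trajectory_dendrogram.nwk").write_text(newick + "\n")
        np.savetxt(out_dir / "trajectory_distances.csv", dist, delimiter=",")
        if comparison.dm and comparison.du:
            tests = trajectories.movement_class_test(
                trajs, comparison.dm, cfg.alpha
            )
            summary["movement_class_tests"] = {
                k: {"p_adjusted": r.p_adjusted, "significant": r.significant}
                for k, r in tests.items()
            }

    @stage("network")
    def _network():
        n_syll = dataset.n_syllables
        nets = {"solitary": [], "dyadic": []}
        cent = {"solitary": [], "dyadic": []}
        for ctx in nets:
            for rec in dataset.by_context(ctx):
                for aid, seq in rec.sequences.items():
                    net = network.transition_matrix(
                        syllables.extract_bouts(seq), n_syll, aid, ctx
                    )
                    nets[ctx].append(net)
                    cent[ctx].append(network.eigenvector_centrality(net).c)
        sol = np.array(cent["solitary"])
        dya = np.array(cent["dyadic"])
        test = network.centrality_context_test(sol, dya, cfg.alpha)
        mod = network.transition_modulation(
            nets["solitary"], nets["dyadic"], state["comparison"].dm,
            cfg.alpha, cfg.min_edge_count,
        )
        pd.DataFrame(
            {
                "syllable": np.arange(n_syll),
                "centrality_solitary": sol.mean(axis=0),
                "centrality_dyadic": dya.mean(axis=0),
            }
        ).to_csv(out_dir / "centrality.csv", index=False)
        pd.DataFrame(mod["edges"]).to_csv(
            out_dir / "edge_tests.csv", index=False
        )
        network.to_graphml(
            out_dir / "network.graphml",
            mod["edges"],
            dya.mean(axis=0) - sol.mean(axis=0),
            test["significant"],
        )
        summary["centrality_significant"] = test["significant"]
        summary["n_significant_edges"] = len(mod["significant"])
        summary["edge_targets_dm_fraction"] = mod["targets_dm_fraction"]
        state["networks"] = nets

    @stage("composition")
    def _composition():
        if not has_annotations:
            manifest["warnings"].append(
                "no annotations: composition stage skipped"
            )
            return
        for ctype in ("active", "passive"):
            try:
                tc = composition.aligned_timecourse(
                    dataset, ctype, cfg, seed=seed
                )
            except Exception as exc:
                manifest["warnings"].append(
                    f"composition ({ctype}): {exc}"
                )
                continue
            pd.DataFrame(
                {
                    "offset": tc.offsets,
                    "dkl_nats": tc.dkl,
                    "z": tc.z,
                    "p": tc.p_values,
                    "significant": tc.significant,
                    "n": tc.n_per_bin,
                }
            ).to_csv(out_dir / f"dkl_timecourse_{ctype}.csv", index=False)
            post = tc.offsets >= 0
            summary[f"dkl_{ctype}_post_onset_significant_fraction"] = float(
                tc.significant[post].mean()
            )
        try:
            jtc = composition.joint_timecourse(dataset, "active", cfg, seed=seed)
            post = jtc.offsets >= 0
            summary["dkl_joint_post_onset_significant_fraction"] = float(
                jtc.significant[post].mean()
            )
        except Exception as exc:
            manifest["warnings"].append(f"joint composition: {exc}")

    @stage("syntax")
    def _syntax():
        if has_annotations:
            for ctype in ("active", "passive"):
                try:
                    tc = syntax.zscore_timecourse(dataset, ctype, cfg)
                except Exception as exc:
                    manifest["warnings"].append(f"syntax ({ctype}): {exc}")
                    continue
                n_sig = int(
                    tc.significant.any(axis=1).sum()
                )
                summary[f"syntaxes_associated_{ctype}"] = n_sig
                summary[f"top_syntaxes_{ctype}"] = [
                    list(s) for s in tc.ranking
                ]
        if not has_tracks:
            return
        fams = [
            syntax.SyntaxFamily((9, 0, 5)),
            syntax.SyntaxFamily((11, 2, 8)),
        ]
        rel_rows = []
        for rec in dataset.by_context("dyadic"):
            try:
                a, b = rec.pair()
            except ValueError:
                continue
            imd = kinematics.imd_series(rec.tracks[a], rec.tracks[b])
            for aid in (a, b):
                occs = syntax.extract_syntaxes(
                    syllables.extract_bouts(rec.sequences[aid]),
                    cfg.syntax_length,
                )
                occ = syntax.family_occupancy(
                    occs, fams, rec.sequences[aid].n_frames
                )
                for ref, mask in occ.items():
                    rel = syntax.rolling_relation(
                        imd, mask, cfg.rolling_window_frames, seed=seed
                    )
                    for _, row in rel["summary"].iterrows():
                        rel_rows.append({"family": str(ref), **row.to_dict()})
        if rel_rows:
            pd.DataFrame(rel_rows).to_csv(
                out_dir / "family_occupancy.csv", index=False
            )

    @stage("classes")
    def _classes():
        if not has_tracks or not dataset.by_context("dyadic"):
            manifest["warnings"].append("classes stage skipped (no dyads)")
            return
        fams = [
            syntax.SyntaxFamily((9, 0, 5)),
            syntax.SyntaxFamily((11, 2, 8)),
        ]
        all_pts = []
        all_tracks_a, all_tracks_b = [], []
        for rec in dataset.by_context("dyadic"):
            a, b = rec.pair()
            imd = kinematics.imd_series(rec.tracks[a], rec.tracks[b])
            all_tracks_a.append(rec.tracks[a].positions)
            all_tracks_b.append(rec.tracks[b].positions)
            for aid in (a, b):
                occs = syntax.extract_syntaxes(
                    syllables.extract_bouts(rec.sequences[aid]),
                    cfg.syntax_length,
                )
                all_pts.extend(kinematics.syntax_kinematics(occs, imd))
        x = np.array([p.x for p in all_pts])
        y = np.array([p.y for p in all_pts])
        labels = kinematics.classify_points(x, y)
        flags = {
            fam.reference: np.array(
                [fam.is_member(p.occurrence.triple) for p in all_pts]
            )
            for fam in fams
        }
        assoc = kinematics.class_family_association(labels, flags, cfg.alpha)
        mat = kinematics.class_dkl_matrix(
            labels, all_pts, dataset.n_syllables
        )
        mat.to_csv(out_dir / "class_dkl_matrix.csv")
        assoc["table"].to_csv(out_dir / "class_family_table.csv")
        controls = kinematics.imd_controls(
            all_tracks_a, all_tracks_b, dataset.recordings[0].tracks[
                dataset.recordings[0].animal_ids[0]
            ].arena_size[0], seed=seed,
        )
        summary["imd_means_mm"] = {
            k: round(v, 1) for k, v in controls["means"].items()
        }
        kde = kinematics.position_kde(
            np.concatenate(all_tracks_a + all_tracks_b)[::10]
        )
        summary["corner_occupancy"] = round(kde["corner_occupancy"], 3)
        summary["class_counts"] = {
            c: int((labels == c).sum())
            for c in kinematics.PRIMARY_CLASSES
        }

    @stage("pca")
    def _pca():
        table = state["table"]
        comparison = state["comparison"]
        res = pca.pca_features(table.frame)
        contrast = None
        if comparison.dm and comparison.du:
            contrast = pca.loading_contrast(res, comparison.dm, 5, cfg.alpha)
            summary["pc_loading_contrast_significant"] = contrast["significant"]
        summary["pc5_variance_fraction"] = float(
            res.variance_ratio[:5].sum()
        )
        ctx = table.meta["context"].to_numpy()
        summary["context_silhouette"] = round(
            pca.context_separation(res.scores, ctx), 3
        )
        lc = table.meta["light_cycle"].to_numpy()
        try:
            summary["light_cycle_silhouette"] = round(
                pca.context_separation(res.scores, lc), 3
            )
        except Exception as exc:
            manifest["warnings"].append(f"light-cycle silhouette: {exc}")
        # standardized variant: robust to the variance-scale gap between
        # high- and low-frequency syllables
        res_s = pca.pca_features(table.frame, scale=True)
        summary["context_silhouette_scaled"] = round(
            pca.context_separation(res_s.scores, ctx), 3
        )
        if comparison.dm and comparison.du:
            summary["pc_loading_contrast_significant_scaled"] = (
                pca.loading_contrast(res_s, comparison.dm, 5, cfg.alpha)[
                    "significant"
                ]
            )
        pd.DataFrame(
            res.loadings,
            index=table.frame.columns,
        ).to_csv(out_dir / "pca_loadings.csv")
        pd.DataFrame(res.scores, index=table.frame.index).to_csv(
            out_dir / "pca_scores.csv"
        )

    manifest["seconds_total"] = round(time.time() - t_start, 3)
    (out_dir / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=1, sort_keys=True) + "\n"
    )
    _write_manifest(out_dir, manifest)
    return summary


def _write_manifest(out_dir: Path, manifest: dict, failed: str | None = None):
    if failed:
        manifest["failed_stage"] = failed
    (Path(out_dir) / "manifest.json").write_text(
        json.dumps(_jsonable(manifest), indent=1, sort_keys=True) + "\n"
    )
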