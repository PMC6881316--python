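"""End-to-end experiment drivers.

Wire the stages together at study scale: simulate the 34-specimen market
survey (204 replicate spectra), preprocess every replicate, fuse consensus
libraries, cluster, run the blind identification test and audit the
commercial labels. Everything is deterministic given the seed; the CLI,
the analysis scripts and the acceptance checks all run through here.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .cluster import (
    Dendrogram,
    SynonymyPolicy,
    concordance,
    cut_by_silhouette,
    distance_matrix,
    linkage_average,
    misidentification_report,
)
from .fixtures import SPECIES, blind_query_design, default_study_config, study_design
from .identify import ScoreParams, blind_test_report
from .msp import MspParams, build_msp
from .preprocess import PreprocessParams, preprocess_pipeline
from .simulate import SimulationConfig, StudySet, generate_panels, simulate_study
from .types import MSP, PeakList

__all__ = [
    "simulate_fixture_study",
    "peaklists_by_specimen",
    "build_specimen_library",
    "build_species_library",
    "cluster_experiment",
    "blind_test_experiment",
    "run_all",
]


def simulate_fixture_study(
    seed: int = 0, config: Optional[SimulationConfig] = None
) -> StudySet:
    """The study-scale fixture: 34 specimens x 6 replicates = 204 spectra."""
    config = config or default_study_config(seed)
    rng = config.rng()
    panels = generate_panels(config, rng, species_names=list(SPECIES))
    return simulate_study(config, study_design(), rng, panels=panels)


def peaklists_by_specimen(
    study: StudySet, params: Optional[PreprocessParams] = None
) -> dict[str, list[PeakList]]:
    """Preprocess every replicate spectrum, grouped by specimen."""
    params = params or PreprocessParams()
    out: dict[str, list[PeakList]] = {}
    for (sid, rep) in sorted(study.spectra):
        pl = preprocess_pipeline(study.spectra[(sid, rep)], params)
        pl.source_id = f"{sid}:{rep}"
        out.setdefault(sid, []).append(pl)
    return out


def build_specimen_library(
    peaklists: Mapping[str, Sequence[PeakList]],
    params: Optional[MspParams] = None,
) -> list[MSP]:
    """One consensus entry per specimen (its six replicate lists)."""
    params = params or MspParams()
    return [build_msp(list(peaklists[sid]), params, label=sid)
            for sid in sorted(peaklists)]


def build_species_library(
    peaklists: Mapping[str, Sequence[PeakList]],
    truth: Mapping[str, str],
    params: Optional[MspParams] = None,
) -> list[MSP]:
    """One consensus entry per species, pooling all its specimens' lists."""
    params = params or MspParams()
    pooled: dict[str, list[PeakList]] = {}
    for sid, pls in peaklists.items():
        pooled.setdefault(truth[sid], []).extend(pls)
    return [build_msp(pooled[sp], params, label=sp) for sp in sorted(pooled)]


def cluster_experiment(
    seed: int = 0,
    config: Optional[SimulationConfig] = None,
    pp_params: Optional[PreprocessParams] = None,
    msp_params: Optional[MspParams] = None,
) -> dict:
    """Simulate the fixture study, build specimen-level consensus spectra,
    cluster them and score species recovery.

    Returns a dict with the study, library, distance matrix, dendrogram,
    the silhouette-selected number of clusters ``k``, flat cluster labels,
    and the adjusted Rand index ``ari`` against the true species.
    """
    study = simulate_fixture_study(seed, config)
    pls = peaklists_by_specimen(study, pp_params)
    library = build_specimen_library(pls, msp_params)
    dm, labels = distance_matrix(library)
    dendro = linkage_average(dm, labels)
    k, flat = cut_by_silhouette(dendro, dm)
    pred = {lab: int(c) for lab, c in zip(labels, flat)}
    ari, purity = concordance(pred, dict(study.truth))
    return {
        "study": study,
        "library": library,
        "distance_matrix": dm,
        "labels": labels,
        "dendrogram": dendro,
        "k": k,
        "flat_labels": pred,
        "ari": ari,
        "purity": purity,
    }


def blind_test_experiment(
    seed: int = 0,
    config: Optional[SimulationConfig] = None,
    pp_params: Optional[PreprocessParams] = None,
    msp_params: Optional[MspParams] = None,
    score_params: Optional[ScoreParams] = None,
) -> dict:
    """The blind identification test at study scale.

    A species-level reference library is fused from the 34-specimen study;
    ten freshly simulated blind-coded specimens (held out of the library)
    are then identified from a single replicate spectrum each. Returns the
    report frame plus the minimum top-hit score among correctly identified
    queries (``min_correct_score``).
    """
    config = config or default_study_config(seed)
    rng = config.rng()
    panels = generate_panels(config, rng, species_names=list(SPECIES))
    study = simulate_study(config, study_design(), rng, panels=panels)
    pls = peaklists_by_specimen(study, pp_params)
    library = build_species_library(pls, study.truth, msp_params)

    blind = simulate_study(config, blind_query_design(), rng, panels=panels)
    queries = {
        sid: preprocess_pipeline(blind.spectra[(sid, "b1t1")],
                                 pp_params or PreprocessParams())
        for sid in blind.truth
    }
    report = blind_test_report(queries, dict(blind.truth), library, score_params)
    correct_scores = report.loc[report["correct"], "score"]
    return {
        "study": study,
        "library": library,
        "report": report,
        "n_correct": report.attrs["n_correct"],
        "n_total": report.attrs["n_total"],
        "min_correct_score": float(correct_scores.min()) if len(correct_scores) else float("nan"),
    }


def run_all(seed: int, outdir, policy: Optional[SynonymyPolicy] = None) -> dict:
    """Full pipeline: simulate -> preprocess -> consensus -> cluster ->
    blind test -> label audit, writing every artifact under ``outdir``.

    Output bytes are a deterministic function of the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    policy = policy or SynonymyPolicy.default()

    clus = cluster_experiment(seed)
    study = clus["study"]
    sio.write_study(study, outdir / "study")

    pls = peaklists_by_specimen(study)
    peaks_dir = outdir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    for sid, lists in sorted(pls.items()):
        for pl in lists:
            sio.write_peaklist_csv(pl, peaks_dir / f"{pl.source_id.replace(':', '_')}.csv")

    sio.write_msp_json(clus["library"], outdir / "library.json")
    pd.DataFrame(
        clus["distance_matrix"], index=clus["labels"], columns=clus["labels"]
    ).to_csv(outdir / "distances.csv", float_format="%.6g")
    sio.write_newick(clus["dendrogram"], clus["labels"], outdir / "dendrogram.nwk")

    blind = blind_test_experiment(seed)
    blind["report"].to_csv(outdir / "blind_test.csv", index=False, float_format="%.4f")

    audit = misidentification_report(study.records, policy)
    audit.to_csv(outdir / "label_audit.csv", index=False)
    audit.attrs["by_marketed"].to_csv(outdir / "label_audit_by_marketed.csv", index=False)

    summary = {
        "seed": int(seed),
        "n_specimens": len(study.records),
        "n_spectra": len(study.spectra),
        "clusters_k": int(clus["k"]),
        "species_ari": round(float(clus["ari"]), 6),
        "blind_correct": int(blind["n_correct"]),
        "blind_total": int(blind["n_total"]),
        "blind_min_correct_score": round(blind["min_correct_score"], 4)
        if np.isfinite(blind["min_correct_score"]) else None,
        "misidentified_n": audit.attrs["n_misidentified"],
        "misidentified_percent": audit.attrs["percent"],
        "policy_mode": policy.mode,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return summary
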