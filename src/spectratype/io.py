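"""File formats: two-column ASCII spectra, CSV peak lists and metadata,
JSON reference libraries, Newick dendrograms.

All readers validate and reject malformed input rather than silently
coercing it; all round-trips are lossless to the stated precision.
"""
from __future__ import annotations

import json
import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .types import MSP, PeakList, RawSpectrum, SpecimenRecord

__all__ = [
    "FormatError",
    "read_spectrum_ascii",
    "write_spectrum_ascii",
    "read_peaklist_csv",
    "write_peaklist_csv",
    "read_msp_json",
    "write_msp_json",
    "read_metadata_csv",
    "write_metadata_csv",
    "write_newick",
    "write_study",
]

MSP_FORMAT_VERSION = 1

_PEAK_COLUMNS = ("mz", "intensity", "snr")


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------- spectra

def read_spectrum_ascii(path) -> RawSpectrum:
    """Read a two-column (m/z, intensity) text spectrum.

    Columns may be separated by whitespace or commas; ``#`` starts a
    comment. Negative intensities are clipped to zero with a warning;
    unsorted rows are sorted with a warning. Non-numeric rows, duplicate
    masses and files with fewer than two points are rejected.
    """
    path = Path(path)
    mzs: list[float] = []
    ints: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = re.split(r"[,\s]+", line)
            if len(parts) != 2:
                raise FormatError(f"{path.name}:{lineno}: expected two columns, got {len(parts)}")
            try:
                mzs.append(float(parts[0]))
                ints.append(float(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: non-numeric value: {line!r}") from exc
    if len(mzs) < 2:
        raise FormatError(f"{path.name}: a spectrum needs at least 2 points, got {len(mzs)}")
    mz = np.asarray(mzs)
    intensity = np.asarray(ints)
    if np.any(intensity < 0):
        warnings.warn(f"{path.name}: negative intensities clipped to 0")
        intensity = np.clip(intensity, 0.0, None)
    if not np.all(np.diff(mz) > 0):
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        dup = np.flatnonzero(np.diff(mz) == 0)
        if dup.size:
            raise FormatError(f"{path.name}: duplicate m/z value {mz[dup[0]]:g}")
        warnings.warn(f"{path.name}: m/z values were not sorted; sorting")
    return RawSpectrum(mz, intensity, meta={"path": str(path)})


def write_spectrum_ascii(spectrum: RawSpectrum, path) -> None:
    path = Path(path)
    meta = spectrum.meta
    with open(path, "w") as fh:
        if "specimen_id" in meta:
            fh.write(f"# specimen_id={meta['specimen_id']} replicate_id={meta.get('replicate_id', '')}\n")
        fh.write("# mz intensity\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{m:.10g} {i:.10g}\n")


# ------------------------------------------------------------- peak lists

def read_peaklist_csv(path) -> PeakList:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    return PeakList(
        df["mz"].to_numpy(float),
        df["intensity"].to_numpy(float),
        df["snr"].to_numpy(float),
        source_id=str(df["source_id"].iloc[0]) if "source_id" in df.columns and len(df) else path.stem,
    )


def write_peaklist_csv(peaks: PeakList, path) -> None:
    df = pd.DataFrame(
        {"mz": peaks.mz, "intensity": peaks.intensity, "snr": peaks.snr,
         "source_id": peaks.source_id}
    )
    df.to_csv(path, index=False, float_format="%.10g")


# ------------------------------------------------------------ MSP library

def write_msp_json(msps: Union[MSP, Sequence[MSP]], path) -> None:
    """Write a reference library (one or more consensus entries) as JSON."""
    if isinstance(msps, MSP):
        msps = [msps]
    doc = {
        "format_version": MSP_FORMAT_VERSION,
        "entries": [
            {
                "label": m.label,
                "n_sources": int(m.n_sources),
                "peaks": [
                    [float(mz), float(mi), float(fr)]
                    for mz, mi, fr in zip(m.mz, m.mean_intensity, m.frequency)
                ],
            }
            for m in msps
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_msp_json(path) -> list[MSP]:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path.name}: not valid JSON: {exc}") from exc
    version = doc.get("format_version")
    if version != MSP_FORMAT_VERSION:
        raise FormatError(
            f"{path.name}: format_version {version!r} != supported {MSP_FORMAT_VERSION}"
        )
    msps = []
    for entry in doc.get("entries", []):
        peaks = np.asarray(entry["peaks"], dtype=float).reshape(-1, 3)
        msps.append(
            MSP(
                label=entry["label"],
                mz=peaks[:, 0],
                mean_intensity=peaks[:, 1],
                frequency=peaks[:, 2],
                n_sources=int(entry["n_sources"]),
            )
        )
    return msps


# --------------------------------------------------------------- metadata

def write_metadata_csv(records: Iterable[SpecimenRecord], path) -> None:
    df = pd.DataFrame([{f: getattr(r, f) for f in SpecimenRecord.FIELDS} for r in records],
                      columns=list(SpecimenRecord.FIELDS))
    df.to_csv(path, index=False)


def read_metadata_csv(path) -> list[SpecimenRecord]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SpecimenRecord.FIELDS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    records = [SpecimenRecord(**{f: row[f] for f in SpecimenRecord.FIELDS})
               for _, row in df.iterrows()]
    ids = [r.specimen_id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path.name}: duplicate specimen_id values")
    return records


# ----------------------------------------------------------------- newick

_NEEDS_QUOTE = re.compile(r"[\s(),:;'\[\]]")


def _newick_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(dendrogram, labels: Sequence[str], path) -> str:
    """Serialize an average-linkage dendrogram as Newick with branch lengths.

    ``dendrogram`` is either a scipy linkage matrix or an object exposing a
    ``linkage`` attribute. Branch lengths are the differences between the
    merge heights of parent and child nodes.
    """
    from scipy.cluster.hierarchy import to_tree

    linkage = np.asarray(getattr(dendrogram, "linkage", dendrogram), dtype=float)
    labels = list(labels)
    if len(labels) != linkage.shape[0] + 1:
        raise FormatError(
            f"{len(labels)} labels for a dendrogram over {linkage.shape[0] + 1} leaves"
        )
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate leaf labels")
    if any(not lab for lab in labels):
        raise FormatError("empty leaf label")

    root = to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{_newick_label(labels[node.id])}:{length:.6g}"
        inner = ",".join(render(c, node.dist) for c in (node.left, node.right))
        return f"({inner}):{length:.6g}"

    inner = ",".join(render(c, root.dist) for c in (root.left, root.right))
    text = f"({inner});\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ------------------------------------------------------------- study sets

def write_study(study, outdir) -> None:
    """Write a simulated study: one ASCII spectrum per replicate plus
    ``metadata.csv`` and ``truth.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spectra_dir = outdir / "spectra"
    spectra_dir.mkdir(exist_ok=True)
    for (sid, rep), spectrum in sorted(study.spectra.items()):
        write_spectrum_ascii(spectrum, spectra_dir / f"{sid}_{rep}.txt")
    write_metadata_csv(study.records, outdir / "metadata.csv")
    truth = pd.DataFrame(
        sorted(study.truth.items()), columns=["specimen_id", "true_species"]
    )
    truth.to_csv(outdir / "truth.csv", index=False)
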