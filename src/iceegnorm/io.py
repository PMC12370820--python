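"""File interchange: segments (EDF or TSV+array pair), contacts,
parcellations and regional maps as TSV.

Segments are read either from EDF (via mne, converted to µV) or from a
plain interchange pair: ``<base>.tsv`` holding channel metadata with
``# fs:`` / ``# subject:`` header comments, next to ``<base>.npy`` or
``<base>.txt`` holding the channels x samples array in µV.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd

from .localisation import Parcellation, Region
from .signal import TimeSeriesSegment


def write_segment(segment: TimeSeriesSegment, base: str,
                  fmt: str = "npy") -> str:
    """Write a segment as the TSV+array interchange pair; returns the
    metadata path."""
    if fmt not in {"npy", "txt"}:
        raise ValueError("fmt must be 'npy' or 'txt'")
    meta_path = base + ".tsv"
    with open(meta_path, "w") as fh:
        fh.write(f"# fs: {segment.fs}\n")
        fh.write(f"# subject: {segment.subject}\n")
        fh.write(f"# data: {os.path.basename(base)}.{fmt}\n")
        pd.DataFrame({"channel": segment.channels}).to_csv(
            fh, sep="\t", index=False)
    if fmt == "npy":
        np.save(base + ".npy", segment.data)
    else:
        np.savetxt(base + ".txt", segment.data)
    return meta_path


def _read_interchange(meta_path: str) -> TimeSeriesSegment:
    meta = {}
    with open(meta_path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    channels = pd.read_csv(meta_path, sep="\t",
                           comment="#")["channel"].tolist()
    base = os.path.splitext(meta_path)[0]
    for ext in (".npy", ".txt"):
        if os.path.exists(base + ext):
            data = (np.load(base + ext) if ext == ".npy"
                    else np.loadtxt(base + ext, ndmin=2))
            break
    else:
        raise FileNotFoundError(f"no data array next to {meta_path}")
    return TimeSeriesSegment(data=data, fs=float(meta["fs"]),
                             channels=channels,
                             subject=meta.get("subject", ""))


def read_segment(path: str, subject: Optional[str] = None) -> TimeSeriesSegment:
    """Read a segment from EDF or from the TSV interchange pair."""
    if path.lower().endswith(".edf"):
        import mne  # heavy import kept local

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data_uv = raw.get_data() * 1e6  # mne returns volts
        return TimeSeriesSegment(data=data_uv, fs=float(raw.info["sfreq"]),
                                 channels=list(raw.ch_names),
                                 subject=subject or "")
    seg = _read_interchange(path if path.endswith(".tsv") else path + ".tsv")
    if subject:
        seg.subject = subject
    return seg


# ---------------------------------------------------------------------------
# contacts and parcellations


def read_contacts(path: str) -> pd.DataFrame:
    """Contacts TSV: subject, contact (or label), x, y, z [, space]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "label" in df.columns and "contact" not in df.columns:
        df = df.rename(columns={"label": "contact"})
    missing = {"subject", "contact", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"contacts file missing columns {sorted(missing)}")
    return df


def write_parcellation(parcellation: Parcellation, path: str) -> None:
    """One row per voxel: region_id, region_name, subcortical, x, y, z."""
    frames = []
    for r in parcellation.regions:
        frames.append(pd.DataFrame({
            "region_id": r.region_id, "region_name": r.name,
            "subcortical": r.subcortical,
            "x": r.voxels[:, 0], "y": r.voxels[:, 1], "z": r.voxels[:, 2]}))
    with open(path, "w") as fh:
        fh.write(f"# atlas: {parcellation.atlas}\n")
        pd.concat(frames, ignore_index=True).to_csv(fh, sep="\t", index=False)


def read_parcellation(path: str) -> Parcellation:
    atlas = "unknown"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# atlas:"):
            atlas = first.split(":", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    regions = []
    for rid, grp in df.groupby("region_id"):
        regions.append(Region(
            region_id=int(rid), name=str(grp["region_name"].iloc[0]),
            voxels=grp[["x", "y", "z"]].to_numpy(dtype=float),
            subcortical=bool(grp["subcortical"].iloc[0])
            if "subcortical" in grp.columns else False))
    return Parcellation(regions=regions, atlas=atlas)


def parcellation_from_nifti(path: str, label_names: dict) -> Parcellation:
    """Convert a NIfTI label volume to voxel-centre region sets.

    ``label_names`` maps integer label -> hemisphere-prefixed region
    name; label 0 is background.
    """
    import nibabel as nib

    img = nib.load(path)
    lab = np.asarray(img.dataobj).astype(int)
    affine = img.affine
    regions = []
    for value, name in sorted(label_names.items()):
        ijk = np.column_stack(np.nonzero(lab == value))
        if len(ijk) == 0:
            continue
        xyz = nib.affines.apply_affine(affine, ijk)
        regions.append(Region(region_id=int(value), name=name, voxels=xyz))
    return Parcellation(regions=regions, atlas=os.path.basename(path))


def read_metadata(path: str) -> pd.DataFrame:
    """Subject metadata TSV: subject, hospital, age, sex."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"subject", "hospital", "age", "sex"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns {sorted(missing)}")
    return df
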