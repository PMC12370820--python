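"""Normative data table construction.

Per-subject per-ROI averaging of contact RBP vectors, exclusion of sparsely
sampled subcortical regions (pallidum, thalamus, accumbens bilaterally on
the standard 82-region atlas, leaving 76), and hemispheric mirroring of
homologous regions (76 -> 38) to increase per-region sample size.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bands import BAND_NAMES
from .localisation import split_hemisphere

logger = logging.getLogger(__name__)

#: Subcortical structures excluded bilaterally from the normative table.
DEFAULT_SUBCORTICAL_EXCLUSIONS = ("pallidum", "thalamus", "accumbens")

TABLE_COLUMNS = ["subject", "hospital", "age", "sex", "roi"] + list(BAND_NAMES)

_SEXES = {"female", "male"}


@dataclass
class NormativeTable:
    """Long-format (subject, hospital, age, sex, ROI) x band RBP records.

    ``regions`` is the full retained region universe (regions may be
    unsampled); ``mirrored`` records whether homologous left/right regions
    have been collapsed.
    """

    df: pd.DataFrame
    regions: List[str]
    mirrored: bool = False
    atlas: str = "synthetic"

    def __post_init__(self) -> None:
        missing = set(TABLE_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"normative table missing columns {sorted(missing)}")
        self.df = self.df[TABLE_COLUMNS].reset_index(drop=True)
        dup = self.df.duplicated(subset=["subject", "roi"])
        if dup.any():
            raise ValueError("more than one row per subject x ROI")
        if (self.df["age"] <= 0).any():
            raise ValueError("ages must be positive")
        bad_sex = set(self.df["sex"]) - _SEXES
        if bad_sex:
            raise ValueError(f"sex must be female/male, got {sorted(bad_sex)}")
        vals = self.df[list(BAND_NAMES)].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite RBP values")
        unknown = set(self.df["roi"]) - set(self.regions)
        if unknown:
            raise ValueError(f"rows reference regions outside the universe: "
                             f"{sorted(unknown)[:5]}")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_subjects(self) -> int:
        return self.df["subject"].nunique()

    def band_rows(self, band: str) -> pd.DataFrame:
        """Rows for one band: metadata columns plus a single ``rbp`` column."""
        if band not in BAND_NAMES:
            raise KeyError(f"unknown band {band!r}")
        out = self.df[["subject", "hospital", "age", "sex", "roi"]].copy()
        out["rbp"] = self.df[band].to_numpy()
        return out


def aggregate_contacts(
    assignments: pd.DataFrame,
    contact_rbp: pd.DataFrame,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Average RBP vectors over a subject's contacts within each ROI.

    Parameters
    ----------
    assignments : output of :func:`iceegnorm.localisation.assign_contacts`
        (possibly after clinical exclusions); excluded contacts are ignored.
    contact_rbp : DataFrame indexed by (subject, contact) or with those
        columns, with the five band columns, each row summing to 1.

    Returns a DataFrame with columns subject, roi (region name) and the
    five band columns, one row per subject x ROI.
    """
    rbp = contact_rbp.reset_index()
    missing = {"subject", "contact", *BAND_NAMES} - set(rbp.columns)
    if missing:
        raise ValueError(f"contact RBP table missing columns {sorted(missing)}")
    sums = rbp[list(BAND_NAMES)].sum(axis=1)
    if not np.allclose(sums, 1.0, atol=atol):
        raise ValueError("contact RBP vectors must sum to 1 per contact")

    kept = assignments.loc[~assignments["excluded"],
                           ["subject", "contact", "region_name"]]
    merged = kept.merge(rbp, on=["subject", "contact"], how="inner")
    if merged.empty:
        warnings.warn("no assigned contacts; empty aggregation", stacklevel=2)
        return pd.DataFrame(columns=["subject", "roi", *BAND_NAMES])
    out = (merged.groupby(["subject", "region_name"], as_index=False)[list(BAND_NAMES)]
           .mean().rename(columns={"region_name": "roi"}))
    return out


def build_normative_table(
    roi_vectors: pd.DataFrame,
    metadata: pd.DataFrame,
    regions: Sequence[str],
    exclude_subcortical: Sequence[str] = DEFAULT_SUBCORTICAL_EXCLUSIONS,
    atlas: str = "synthetic",
) -> NormativeTable:
    """Join subject metadata and drop excluded subcortical regions.

    ``exclude_subcortical`` lists hemisphere-free base names excluded in
    both hemispheres; on the standard 82-region atlas the default
    (pallidum, thalamus, accumbens) reduces the universe to 76 regions.

    Parameters
    ----------
    roi_vectors : output of :func:`aggregate_contacts`.
    metadata : DataFrame with columns subject, hospital, age, sex covering
        every subject present in ``roi_vectors``.
    regions : the atlas's full region-name universe.
    """
    meta = metadata.set_index("subject") if "subject" in metadata.columns else metadata
    missing_cols = {"hospital", "age", "sex"} - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns {sorted(missing_cols)}")
    missing = set(roi_vectors.get("subject", pd.Series(dtype=object))) - set(meta.index)
    if missing:
        raise ValueError(f"subject(s) missing metadata: {sorted(missing)}")

    excluded_bases = set(exclude_subcortical)
    keep_regions = [r for r in regions
                    if split_hemisphere(r)[1] not in excluded_bases]
    dropped = len(regions) - len(keep_regions)
    logger.info("excluded %d subcortical regions; universe %d -> %d",
                dropped, len(regions), len(keep_regions))

    rows = roi_vectors[roi_vectors["roi"].isin(keep_regions)].copy()
    rows = rows.merge(meta[["hospital", "age", "sex"]], left_on="subject",
                      right_index=True, how="left")
    return NormativeTable(df=rows[TABLE_COLUMNS] if not rows.empty
                          else pd.DataFrame(columns=TABLE_COLUMNS),
                          regions=keep_regions, mirrored=False, atlas=atlas)


def mirror_table(
    table: NormativeTable,
    homologous_map: Optional[Mapping[str, str]] = None,
    rule: str = "mean",
) -> NormativeTable:
    """Collapse homologous left/right regions into mirrored regions.

    Justified by the reported left/right symmetry of relative band power;
    halves the region universe (76 -> 38 on the standard atlas) and gives
    each mirrored region markedly more subjects.  A subject implanted
    bilaterally in a symmetric pair contributes exactly one row per
    mirrored region, combined per band by ``rule``:

    - ``"mean"`` (default): arithmetic mean of the left and right vectors,
    - ``"left"`` / ``"right"``: keep that hemisphere's vector.

    ``homologous_map`` maps region name -> mirrored base name for atlases
    whose names lack recognisable left/right prefixes.
    """
    if table.mirrored:
        raise ValueError("table is already mirrored")
    if rule not in {"mean", "left", "right"}:
        raise ValueError(f"unknown mirroring rule {rule!r}")

    def base_of(name: str) -> str:
        if homologous_map is not None:
            if name not in homologous_map:
                raise ValueError(f"region {name!r} missing from homologous map")
            return homologous_map[name]
        hemi, base = split_hemisphere(name)
        if hemi is None:
            raise ValueError(f"region {name!r} has no hemisphere prefix and "
                             "no homologous map was given")
        return base

    def hemi_of(name: str) -> str:
        hemi, _ = split_hemisphere(name)
        return hemi or ""

    new_regions = sorted({base_of(r) for r in table.regions})
    if len(new_regions) * 2 != len(table.regions):
        raise ValueError("homologous map is not a perfect left/right matching")

    df = table.df.copy()
    if df.empty:
        out = df.copy()
        out["roi"] = out["roi"].map(base_of)
    else:
        df["roi"] = df["roi"].map(base_of)
        if rule in {"left", "right"}:
            hemis = table.df["roi"].map(hemi_of)
            pref = (hemis == rule)
            # keep preferred hemisphere where present, otherwise the other
            df["_pref"] = (~pref).astype(int)
            df = (df.sort_values("_pref")
                    .drop_duplicates(subset=["subject", "roi"], keep="first")
                    .drop(columns="_pref"))
            out = df
        else:
            meta = df.groupby(["subject", "roi"], as_index=False).first()[
                ["subject", "roi", "hospital", "age", "sex"]]
            vals = df.groupby(["subject", "roi"], as_index=False)[list(BAND_NAMES)].mean()
            out = meta.merge(vals, on=["subject", "roi"])
    return NormativeTable(df=out[TABLE_COLUMNS] if not out.empty
                          else pd.DataFrame(columns=TABLE_COLUMNS),
                          regions=new_regions, mirrored=True, atlas=table.atlas)


# ---------------------------------------------------------------------------
# TSV serialisation

def write_table(table: NormativeTable, path, version: str = "") -> None:
    """Write a normative table as TSV with a commented header block."""
    with open(path, "w") as fh:
        fh.write(f"# atlas: {table.atlas}\n")
        fh.write(f"# mirrored: {str(table.mirrored).lower()}\n")
        fh.write(f"# n_regions: {table.n_regions}\n")
        fh.write(f"# regions: {','.join(table.regions)}\n")
        if version:
            fh.write(f"# version: {version}\n")
        table.df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> NormativeTable:
    meta: Dict[str, str] = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                body_lines.append(line)
    df = pd.read_csv(io.StringIO("".join(body_lines)), sep="\t")
    regions = meta.get("regions", "")
    return NormativeTable(
        df=df,
        regions=regions.split(",") if regions else sorted(df["roi"].unique()),
        mirrored=meta.get("mirrored", "false") == "true",
        atlas=meta.get("atlas", "unknown"),
    )
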