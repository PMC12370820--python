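"""Contact-to-region assignment under the 5 mm nearest-grey-matter rule.

Each electrode contact is assigned to the region owning its nearest
grey-matter voxel centre (Euclidean distance in mm); contacts farther than
``max_dist`` from every voxel are excluded.  Contacts inside known lesions,
inside the seizure onset zone, or later resected are excluded by clinical
flags so that only presumed-healthy tissue enters the normative table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

CLINICAL_REASONS = ("lesion", "soz", "resected")

HEMI_PREFIXES = (("Left-", "Right-"), ("left_", "right_"), ("lh.", "rh."),
                 ("L_", "R_"))


@dataclass
class Region:
    """One parcel: an id, a hemisphere-prefixed name and its voxel centres."""

    region_id: int
    name: str
    voxels: np.ndarray  # (m, 3) voxel centre coordinates, mm
    subcortical: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float).reshape(-1, 3)
        if self.voxels.shape[0] == 0:
            raise ValueError(f"region {self.name!r} has no voxels")


def split_hemisphere(name: str) -> Tuple[Optional[str], str]:
    """Return (hemisphere, base name); hemisphere None when unprefixed."""
    for left, right in HEMI_PREFIXES:
        if name.startswith(left):
            return "left", name[len(left):]
        if name.startswith(right):
            return "right", name[len(right):]
    return None, name


@dataclass
class Parcellation:
    """A labelled grey-matter voxel parcellation with homologous pairs."""

    regions: List[Region]
    atlas: str = "synthetic"
    homologous_override: Optional[Dict[int, int]] = None

    _by_id: Dict[int, Region] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("parcellation has no regions")
        self._by_id = {r.region_id: r for r in self.regions}
        if len(self._by_id) != len(self.regions):
            raise ValueError("duplicate region ids")

    def __len__(self) -> int:
        return len(self.regions)

    def region(self, region_id: int) -> Region:
        return self._by_id[region_id]

    @property
    def names(self) -> List[str]:
        return [r.name for r in self.regions]

    def homologous_pairs(self) -> Dict[int, int]:
        """Symmetric left<->right id map derived from name prefixes.

        An explicit ``homologous_override`` wins over prefix matching.
        Raises when a hemisphere-prefixed region lacks a partner.
        """
        if self.homologous_override is not None:
            pairs = dict(self.homologous_override)
            pairs.update({v: k for k, v in self.homologous_override.items()})
            return pairs
        by_base: Dict[str, Dict[str, int]] = {}
        for r in self.regions:
            hemi, base = split_hemisphere(r.name)
            if hemi is None:
                raise ValueError(
                    f"region {r.name!r} has no recognised hemisphere prefix; "
                    "provide homologous_override"
                )
            by_base.setdefault(base, {})[hemi] = r.region_id
        pairs: Dict[int, int] = {}
        for base, hemis in by_base.items():
            if set(hemis) != {"left", "right"}:
                raise ValueError(f"region base {base!r} lacks a homologue")
            pairs[hemis["left"]] = hemis["right"]
            pairs[hemis["right"]] = hemis["left"]
        return pairs


# ---------------------------------------------------------------------------
# assignment

ASSIGNMENT_COLUMNS = ["subject", "contact", "region_id", "region_name",
                      "distance_mm", "excluded", "reasons"]


def assign_contacts(
    contacts: pd.DataFrame,
    parcellation: Parcellation,
    max_dist: float = 5.0,
) -> pd.DataFrame:
    """Assign each contact to its nearest grey-matter region within 5 mm.

    Parameters
    ----------
    contacts : DataFrame with columns subject, contact, x, y, z (mm).
    parcellation : Parcellation sharing the contacts' coordinate space.
    max_dist : maximal contact-to-voxel-centre distance, mm.

    Distance ties are broken deterministically towards the lowest region
    id, then the lowest voxel index within that region.

    Returns a DataFrame with one row per contact: assigned region (or NA),
    distance to the nearest voxel, and an ``excluded`` flag with reason
    ``"too far"`` when the nearest grey matter lies beyond ``max_dist``.
    """
    if len(parcellation) == 0:
        raise ValueError("empty parcellation")
    required = {"subject", "contact", "x", "y", "z"}
    missing = required - set(contacts.columns)
    if missing:
        raise ValueError(f"contacts table missing columns {sorted(missing)}")

    # voxels ordered by (region_id, voxel index) -> global index order is the
    # lexicographic tie-break order
    regions_sorted = sorted(parcellation.regions, key=lambda r: r.region_id)
    all_vox = np.vstack([r.voxels for r in regions_sorted])
    vox_region = np.concatenate(
        [np.full(len(r.voxels), r.region_id) for r in regions_sorted])
    tree = cKDTree(all_vox)

    pts = contacts[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite contact coordinates")
    dists, idx = tree.query(pts)

    rows = []
    for i, (_, c) in enumerate(contacts.iterrows()):
        d = float(dists[i])
        # resolve exact ties deterministically: earliest voxel in
        # (region id, voxel index) order among all at minimal distance
        cand = tree.query_ball_point(pts[i], d + 1e-9)
        j = min(cand) if cand else int(idx[i])
        rid = int(vox_region[j])
        if d > max_dist:
            rows.append((c["subject"], c["contact"], pd.NA, pd.NA, d, True,
                         "too far"))
        else:
            rows.append((c["subject"], c["contact"], rid,
                         parcellation.region(rid).name, d, False, ""))
    out = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    out["region_id"] = out["region_id"].astype("Int64")
    return out


def apply_channel_exclusions(
    assignments: pd.DataFrame,
    clinical_flags: Mapping[Tuple[str, str], Iterable[str]],
) -> pd.DataFrame:
    """Exclude contacts flagged as lesional, seizure-onset-zone or resected.

    ``clinical_flags`` maps (subject, contact) to an iterable of reasons
    drawn from {"lesion", "soz", "resected"}.  Reasons accumulate
    (set-union) with any existing exclusion reasons.
    """
    out = assignments.copy()
    keys = set(zip(out["subject"], out["contact"]))
    for key, reasons in clinical_flags.items():
        if key not in keys:
            raise KeyError(f"unknown contact {key!r} in clinical flags")
        reasons = sorted(set(reasons))
        bad = set(reasons) - set(CLINICAL_REASONS)
        if bad:
            raise ValueError(f"unknown exclusion reasons {sorted(bad)}")
        sel = (out["subject"] == key[0]) & (out["contact"] == key[1])
        for ridx in out.index[sel]:
            existing = [r for r in str(out.at[ridx, "reasons"]).split(";") if r]
            merged = sorted(set(existing) | set(reasons))
            out.at[ridx, "reasons"] = ";".join(merged)
            out.at[ridx, "excluded"] = True
    return out
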