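"""Structural microenvironment and relative solvent accessibility.

The structural environment of a variant is the normalized residue-type
composition of all protein residues whose C-alpha lies within a 6 A sphere of
the wild-type residue's C-alpha (the center residue itself excluded).  RSA is
the DSSP absolute accessible surface divided by a per-residue-type theoretical
maximum (Gly-X-Gly table), clamped to [0, 1].  A rolling-probe surface sampler
is provided as a fallback when no accessibility file is supplied; the
file-based path is authoritative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigError, IntegrityError, MappingError, SapgoError
from .io_formats import (
    AccessibilityRecord,
    Residue,
    StructureModel,
    VariantRecord,
)
from .residues import AA_INDEX, MAX_ASA_GXG, ONE_TO_THREE, THREE_TO_ONE

DEFAULT_RADIUS = 6.0


@dataclass(frozen=True)
class ResidueHandle:
    """A located residue: chain id plus the residue object."""

    chain_id: str
    residue: Residue


@dataclass(frozen=True)
class EnvComposition:
    """20 neighbor-type frequencies (alphabetical order) and the neighbor count."""

    frequencies: tuple[float, ...]
    neighbor_count: int

    def __post_init__(self) -> None:
        if len(self.frequencies) != 20:
            raise IntegrityError("environment composition must have 20 entries")
        total = sum(self.frequencies)
        if self.neighbor_count > 0 and abs(total - 1.0) > 1e-9:
            raise IntegrityError("non-empty composition must sum to 1")
        if self.neighbor_count == 0 and abs(total) > 1e-9:
            raise IntegrityError("empty composition must be all zeros")


def map_variant_to_structure(
    variant: VariantRecord,
    model: StructureModel,
    chain_id: str,
    mapping: Optional[dict[int, int]] = None,
) -> ResidueHandle:
    """Locate the structure residue for a sequence variant.

    By default sequence position == PDB residue number; an explicit
    ``{sequence position -> residue number}`` table overrides.  The residue
    type found in the structure must match the variant's wild type.
    """
    resnum = variant.pos if mapping is None else mapping.get(variant.pos)
    if resnum is None:
        raise MappingError(
            f"{variant.token}: position {variant.pos} absent from the mapping table"
        )
    try:
        residue = model.residue(chain_id, resnum)
    except SapgoError as exc:
        raise MappingError(f"{variant.token}: {exc}") from exc
    found_one = THREE_TO_ONE.get(residue.name, "X")
    if found_one != variant.wt:
        raise MappingError(
            f"{variant.token}: expected {ONE_TO_THREE.get(variant.wt, variant.wt)} "
            f"at {chain_id}/{resnum}, found {residue.name}"
        )
    return ResidueHandle(chain_id=chain_id, residue=residue)


def structural_environment(
    model: StructureModel,
    center: ResidueHandle,
    radius: float = DEFAULT_RADIUS,
    same_chain_only: bool = False,
) -> EnvComposition:
    """Residue-type composition within ``radius`` A of the center C-alpha.

    Neighbors are protein residues (all chains unless restricted) with a
    C-alpha at Euclidean distance <= radius, excluding the center itself;
    non-standard residue types are ignored.
    """
    center_ca = center.residue.ca
    if center_ca is None:
        raise MappingError(
            f"residue {center.chain_id}/{center.residue.number} lacks a C-alpha atom"
        )
    counts = np.zeros(20, dtype=float)
    n_neighbors = 0
    for chain_id, res in model.all_residues():
        if same_chain_only and chain_id != center.chain_id:
            continue
        if chain_id == center.chain_id and res.key == center.residue.key:
            continue
        ca = res.ca
        if ca is None:
            continue
        if float(np.linalg.norm(ca - center_ca)) <= radius:
            one = THREE_TO_ONE.get(res.name)
            if one is not None:
                counts[AA_INDEX[one]] += 1
                n_neighbors += 1
    if n_neighbors > 0:
        counts /= counts.sum()
    return EnvComposition(frequencies=tuple(counts.tolist()), neighbor_count=n_neighbors)


@dataclass(frozen=True)
class RsaValue:
    """Relative solvent accessibility, clamped to [0, 1]."""

    rsa: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rsa <= 1.0:
            raise IntegrityError(f"RSA {self.rsa} outside [0,1]")


def relative_accessibility(
    acc: AccessibilityRecord,
    handle: ResidueHandle,
    reference: Optional[dict[str, float]] = None,
    missing_policy: str = "error",
) -> RsaValue:
    """ACC / maxASA(residue type), clamped to [0, 1].

    ``missing_policy``: ``"error"`` (default) raises when the residue is
    absent from the accessibility record; ``"impute"`` returns 0.5 with a
    warning.
    """
    reference = reference if reference is not None else MAX_ASA_GXG
    value = acc.get(handle.chain_id, handle.residue.number)
    if value is None:
        if missing_policy == "impute":
            warnings.warn(
                f"no accessibility for {handle.chain_id}/{handle.residue.number}; "
                "imputing RSA = 0.5"
            )
            return RsaValue(rsa=0.5)
        raise MappingError(
            f"residue {handle.chain_id}/{handle.residue.number} absent from "
            "the accessibility record"
        )
    one = THREE_TO_ONE.get(handle.residue.name)
    if one is None or one not in reference:
        raise ConfigError(f"no reference maximum ASA for residue {handle.residue.name}")
    return RsaValue(rsa=min(1.0, max(0.0, value / reference[one])))


# ---------------------------------------------------------------------------
# Rolling-probe fallback for absolute accessibility
# ---------------------------------------------------------------------------

_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
_DEFAULT_VDW = 1.70


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-section spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def compute_accessibility(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 120,
) -> AccessibilityRecord:
    """Rolling-probe (Shrake-Rupley style) accessible surface per residue, A^2.

    Sphere points on each atom's solvent-expanded surface are tested for
    occlusion by every other atom; the accessible fraction times the sphere
    area, summed over a residue's atoms, is its absolute ASA.  This sampler is
    a coarse fallback; DSSP files remain the authoritative source.
    """
    atoms: list[tuple[str, tuple[int, str], np.ndarray, float]] = []
    for chain_id, res in model.all_residues():
        for name, coord in res.atoms.items():
            radius = _VDW_RADII.get(name[0], _DEFAULT_VDW) + probe_radius
            atoms.append((chain_id, res.key, coord, radius))
    if not atoms:
        return AccessibilityRecord(acc={})
    coords = np.array([a[2] for a in atoms])
    radii = np.array([a[3] for a in atoms])
    unit = _sphere_points(n_points)
    acc: dict[tuple[str, int], float] = {}
    for i, (chain_id, key, coord, radius) in enumerate(atoms):
        points = coord + radius * unit
        buried = np.zeros(len(points), dtype=bool)
        d2 = ((coords - coord) ** 2).sum(axis=1)
        near = np.where((d2 < (radii + radius) ** 2) & (np.arange(len(atoms)) != i))[0]
        for j in near:
            buried |= ((points - coords[j]) ** 2).sum(axis=1) < radii[j] ** 2
        frac = 1.0 - buried.mean()
        area = frac * 4.0 * np.pi * radius ** 2
        acc_key = (chain_id, key[0])
        acc[acc_key] = acc.get(acc_key, 0.0) + area
    return AccessibilityRecord(acc=acc)
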