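"""Assembly of the SVM input vectors.

The full sequence preset is a 51-element vector: mutation block (20),
sequence-environment frequencies (20), profile features (5), PANTHER features
(4) and GO features (2).  The full structure preset replaces the sequence
environment with the structural environment and inserts one RSA element,
giving 52 elements.  Reduced profile-only presets (45 / 46 elements) serve as
ablations standing in for the historical profile+environment predictors.

Block order is fixed and versioned in the layout tag; the mutation block is
+/-1, every other element lies in [0, 1] (the raw GO log-odds score is
squashed through tanh before entering the vector).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, FormatError, IntegrityError
from .go_function import GO_COUNT_SCALE_K, GoFeatures
from .io_formats import PantherRecord
from .profiles import ProfileFeatures, saturation_scale
from .residues import AA_INDEX, STANDARD_AA
from .structure_env import EnvComposition, RsaValue

LAYOUT_VERSION = "v1"

#: Squash scale for the raw GO log-odds score entering the SVM vector.
GO_SCORE_SQUASH = 10.0

#: PANTHER independent-count saturation scale.
PANTHER_COUNT_SCALE_K = 100.0


@dataclass(frozen=True)
class FeaturePreset:
    """A named block layout."""

    name: str
    blocks: tuple[tuple[str, int], ...]  # (block name, width) in vector order

    @property
    def length(self) -> int:
        return sum(width for _, width in self.blocks)

    @property
    def layout_tag(self) -> str:
        blocks = "+".join(f"{name}{width}" for name, width in self.blocks)
        return f"{self.name}/{LAYOUT_VERSION}:{blocks}"


PRESETS: dict[str, FeaturePreset] = {
    "snpsgo_seq": FeaturePreset(
        "snpsgo_seq",
        (("mut", 20), ("seq_env", 20), ("profile", 5), ("panther", 4), ("go", 2)),
    ),
    "snpsgo_3d": FeaturePreset(
        "snpsgo_3d",
        (("mut", 20), ("struct_env", 20), ("rsa", 1), ("profile", 5), ("panther", 4), ("go", 2)),
    ),
    "profile_seq": FeaturePreset(
        "profile_seq", (("mut", 20), ("seq_env", 20), ("profile", 5))
    ),
    "profile_3d": FeaturePreset(
        "profile_3d", (("mut", 20), ("struct_env", 20), ("rsa", 1), ("profile", 5))
    ),
}


def get_preset(name: str) -> FeaturePreset:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[name]


@dataclass(frozen=True)
class FeatureVector:
    """An assembled SVM input with its versioned layout tag."""

    values: tuple[float, ...]
    layout_tag: str

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in self.values):
            raise IntegrityError("feature vector contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def encode_mutation(wt: str, mut: str) -> tuple[float, ...]:
    """20-element block: -1 at the wild type index, +1 at the mutant index.

    Residue order is alphabetical by one-letter code, versioned in the layout
    tag.  Ambiguity codes are rejected (the variant is unpredictable).
    """
    if wt == mut:
        raise FormatError(f"identity substitution {wt}->{mut}")
    if wt not in AA_INDEX or mut not in AA_INDEX:
        raise FormatError(
            f"cannot encode non-standard residue in substitution {wt}->{mut}"
        )
    block = [0.0] * 20
    block[AA_INDEX[wt]] = -1.0
    block[AA_INDEX[mut]] = 1.0
    return tuple(block)


def sequence_environment(
    sequence: str, pos: int, window: int = 19
) -> tuple[float, ...]:
    """Residue frequencies in a window centered at ``pos`` (1-based).

    The window spans pos-(w-1)/2 .. pos+(w-1)/2 inclusive of the central
    residue, truncated at the termini; ambiguity codes count neither in the
    numerator nor the denominator.
    """
    if window % 2 == 0:
        raise ConfigError(f"window must be odd, got {window}")
    if not 1 <= pos <= len(sequence):
        raise IntegrityError(f"position {pos} outside sequence length {len(sequence)}")
    half = window // 2
    start = max(0, pos - 1 - half)
    end = min(len(sequence), pos + half)
    counts = [0.0] * 20
    total = 0
    for aa in sequence[start:end]:
        idx = AA_INDEX.get(aa)
        if idx is not None:
            counts[idx] += 1
            total += 1
    if total > 0:
        counts = [c / total for c in counts]
    return tuple(counts)


def panther_features(record: Optional[PantherRecord]) -> tuple[float, ...]:
    """4-element PANTHER block with the fixed fallback (0.5, 0, 0, 0).

    Present records pass through (P(deleterious), f_wt, f_mut) and
    saturation-scale the independent-count field; there is no
    presence-indicator element.
    """
    if record is None:
        return (0.5, 0.0, 0.0, 0.0)
    return (
        record.p_deleterious,
        record.f_wt,
        record.f_mut,
        saturation_scale(record.n_independent_counts, PANTHER_COUNT_SCALE_K),
    )


def go_block(features: GoFeatures) -> tuple[float, ...]:
    """(squashed GO score, scaled term count); the (0,0) fallback survives."""
    score, count_scaled = features.go_score, saturation_scale(
        float(features.n_terms), GO_COUNT_SCALE_K
    )
    return (math.tanh(score / GO_SCORE_SQUASH), count_scaled)


def assemble(preset: FeaturePreset | str, **blocks: Sequence[float]) -> FeatureVector:
    """Concatenate blocks in the preset's fixed order and stamp the tag.

    Block keyword names must match the preset (``mut``, ``seq_env``,
    ``struct_env``, ``rsa``, ``profile``, ``panther``, ``go``); each must have
    the declared width.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    values: list[float] = []
    for name, width in preset.blocks:
        if name not in blocks:
            raise ConfigError(f"preset {preset.name}: missing block {name!r}")
        block = tuple(float(v) for v in blocks[name])
        if len(block) != width:
            raise ConfigError(
                f"preset {preset.name}: block {name!r} has {len(block)} elements, "
                f"expected {width}"
            )
        values.extend(block)
    extra = set(blocks) - {name for name, _ in preset.blocks}
    if extra:
        raise ConfigError(f"preset {preset.name}: unexpected blocks {sorted(extra)}")
    return FeatureVector(values=tuple(values), layout_tag=preset.layout_tag)


def assemble_variant(
    preset: FeaturePreset | str,
    wt: str,
    mut: str,
    profile: ProfileFeatures,
    sequence: Optional[str] = None,
    pos: Optional[int] = None,
    struct_env: Optional[EnvComposition] = None,
    rsa: Optional[RsaValue] = None,
    panther: Optional[PantherRecord] = None,
    go: Optional[GoFeatures] = None,
) -> FeatureVector:
    """Convenience wrapper computing per-block encodings for one variant."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    blocks: dict[str, Sequence[float]] = {
        "mut": encode_mutation(wt, mut),
        "profile": profile.as_tuple(),
    }
    needed = {name for name, _ in preset.blocks}
    if "seq_env" in needed:
        if sequence is None or pos is None:
            raise ConfigError("sequence preset requires sequence and position")
        blocks["seq_env"] = sequence_environment(sequence, pos)
    if "struct_env" in needed:
        if struct_env is None:
            raise ConfigError("structure preset requires a structural environment")
        blocks["struct_env"] = struct_env.frequencies
    if "rsa" in needed:
        if rsa is None:
            raise ConfigError("structure preset requires an RSA value")
        blocks["rsa"] = (rsa.rsa,)
    if "panther" in needed:
        blocks["panther"] = panther_features(panther)
    if "go" in needed:
        blocks["go"] = go_block(go if go is not None else GoFeatures(0.0, 0))
    return assemble(preset, **blocks)
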