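"""In silico random Fc variant libraries.

Libraries are drawn over the 21 Fc interface positions the feature set
covers: ``mut3`` and ``mut5`` libraries carry a fixed number of random
substitutions (positions sampled uniformly without replacement, target
amino acid uniform over the 19 non-wild-type residues), while the
``mut8`` library draws six to eight mutations restricted to an
allowlist of substitutions that are not strongly destabilizing on
their own, as estimated from single-mutation records of the curated
dataset.

Generation is seed-deterministic and deduplicates by signature until
the requested library size is reached.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemistry import CANONICAL_AA
from .interface_features import FC_POSITIONS
from .mutator import Mutation, VariantSpec, parse_mutations
from .structure_io import ChainRole, ComplexModel

# A single mutation raising log10 KD by more than this (i.e. weakening
# binding by more than ~3-fold) is considered destabilizing and is
# excluded from the constrained library.
DEFAULT_DESTABILIZATION_THRESHOLD = 0.5

_MAX_ATTEMPT_FACTOR = 100


class GenerationError(ValueError):
    pass


@dataclasses.dataclass
class LibrarySpec:
    n_variants: int
    n_mutations: int | tuple[int, int]
    positions: tuple[int, ...] = FC_POSITIONS
    allowlist: Mapping[int, tuple[str, ...]] | None = None
    seed: int = 0

    def sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_mutations, int):
            return (self.n_mutations,)
        lo, hi = self.n_mutations
        return tuple(range(lo, hi + 1))

    def __post_init__(self):
        if max(self.sizes()) > len(self.positions):
            raise GenerationError("n_mutations exceeds available positions")


def wild_type_from_model(model: ComplexModel,
                         positions: Sequence[int] = FC_POSITIONS) -> dict[int, str]:
    """Wild-type amino acid per EU position, read off the reference."""
    return {pos: model.site(ChainRole.FC, pos).amino_acid for pos in positions}


def random_library(spec: LibrarySpec,
                   wild_type: Mapping[int, str]) -> list[VariantSpec]:
    """Draw ``spec.n_variants`` unique variants.

    Positions are sampled uniformly without replacement; the target
    amino acid is uniform over the allowed set at that position (all 19
    non-wild-type residues unless an allowlist restricts it).  Sampling
    repeats until the requested number of unique signatures exists,
    failing after 100x ``n_variants`` attempts."""
    rng = np.random.default_rng(spec.seed)
    positions = np.array(spec.positions)
    for pos in positions:
        if pos not in wild_type:
            raise GenerationError(f"no wild-type amino acid for position {pos}")
    choices: dict[int, list[str]] = {}
    for pos in positions:
        if spec.allowlist is not None:
            allowed = [a for a in spec.allowlist.get(int(pos), ())
                       if a != wild_type[pos]]
            if not allowed:
                raise GenerationError(f"empty allowlist at position {pos}")
        else:
            allowed = sorted(CANONICAL_AA - {wild_type[pos]})
        choices[int(pos)] = allowed

    sizes = spec.sizes()
    out: list[VariantSpec] = []
    seen: set[frozenset[Mutation]] = set()
    attempts = 0
    max_attempts = _MAX_ATTEMPT_FACTOR * spec.n_variants
    while len(out) < spec.n_variants:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not generate {spec.n_variants} unique variants "
                f"in {max_attempts} attempts"
            )
        size = sizes[0] if len(sizes) == 1 else int(rng.choice(sizes))
        picked = rng.choice(positions, size=size, replace=False)
        mutations = frozenset(
            Mutation(int(pos), wild_type[int(pos)],
                     choices[int(pos)][int(rng.integers(len(choices[int(pos)])))])
            for pos in sorted(picked)
        )
        if mutations in seen:
            continue
        seen.add(mutations)
        out.append(VariantSpec(mutations))
    return out


def constrained_library(spec: LibrarySpec,
                        singles_table: Mapping[str, float],
                        wild_type: Mapping[int, str],
                        threshold: float = DEFAULT_DESTABILIZATION_THRESHOLD
                        ) -> list[VariantSpec]:
    """Library restricted to substitutions whose single-mutation effect
    on log10 KD is below ``threshold`` (not strongly destabilizing).

    ``singles_table`` maps mutation strings (e.g. ``"N434Y"``) to the
    estimated change in log10 KD of that mutation alone.  The allowlist
    must cover at least as many positions as the largest library size.
    """
    allow: dict[int, list[str]] = {}
    for token, effect in singles_table.items():
        if effect >= threshold:
            continue
        parsed = parse_mutations(token).mutations
        if len(parsed) != 1:
            raise GenerationError(f"{token!r} is not a single mutation")
        mut = next(iter(parsed))
        allow.setdefault(mut.eu_position, []).append(mut.mut_aa)
    need = max(spec.sizes())
    if len(allow) < need:
        raise GenerationError(
            f"allowlist covers {len(allow)} positions; "
            f"{need} are required for the largest variants"
        )
    constrained = dataclasses.replace(
        spec,
        positions=tuple(sorted(allow)),
        allowlist={p: tuple(sorted(a)) for p, a in allow.items()},
    )
    return random_library(constrained, wild_type)


def distribution_summary(predictions: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Descriptive statistics of predicted log10 KD per library."""
    rows = []
    for name, values in predictions.items():
        v = np.asarray(values, float)
        if v.size == 0:
            raise GenerationError(f"library {name!r} has no predictions")
        rows.append({
            "library": name, "n": int(v.size),
            "mean": float(v.mean()), "std": float(v.std(ddof=0)),
            "min": float(v.min()), "max": float(v.max()),
        })
    return pd.DataFrame(rows).set_index("library")


def library_to_frame(specs: Sequence[VariantSpec]) -> pd.DataFrame:
    """Variant-table dialect frame for round-tripping into curation."""
    return pd.DataFrame({
        "mutations": [str(s) for s in specs],
        "kd_molar": np.nan,
        "ph": 7.0,
        "method": "SPR",
        "binder_flag": "unmeasured",
    })
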