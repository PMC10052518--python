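"""Build the learning sets from a raw variant/affinity table.

The raw material is a delimited table of Fc variants with a measured
dissociation constant (molar), the assay pH (6.0 or 7.0) and the assay
method.  Curation applies three steps:

* **pH harmonization** — affinities reported at pH 6.0 only are mapped
  to a pH 7.0 scale by multiplying KD by a constant factor.  The default
  factor is derived from the wild-type Fc, whose KD is 1.3e-6 M at
  pH 6.0 and 8.8e-5 M at pH 7.0, giving round(8.8e-5 / 1.3e-6) = 68;
  the log(KD)-vs-pH relation is approximately linear in this range, so
  a single multiplicative constant is a reasonable first-order model.
* **effective-signature deduplication** — only mutations at catalog
  positions enter the structural features, so two variants differing
  only at off-catalog positions are indistinguishable to the model and
  would bias training; the first occurrence is kept.
* **learning-set split** — the first learning set (FLS) keeps only the
  homogeneous pH 7.0 SPR measurements; the second (SLS) adds the
  harmonized pH 6.0 records.

Responses are modeled throughout as log10 KD.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import math
from typing import Iterable, Sequence

import pandas as pd

from .mutator import VariantSpec, parse_mutations

logger = logging.getLogger(__name__)

# Wild-type Fc dissociation constants (molar) used to derive the
# default pH-harmonization factor.
KD_WT_PH7 = 8.8e-5
KD_WT_PH6 = 1.3e-6

VALID_METHODS = ("SPR", "ELISA", "ALPHA")


class CurationError(ValueError):
    pass


def default_harmonization_factor(kd_ph7: float = KD_WT_PH7,
                                 kd_ph6: float = KD_WT_PH6) -> int:
    """Integer ratio of wild-type KD at pH 7.0 to pH 6.0 (default 68)."""
    return round(kd_ph7 / kd_ph6)


@dataclasses.dataclass
class VariantRecord:
    """One raw measurement: variant, KD (molar), assay pH and method."""

    spec: VariantSpec
    kd: float | None
    ph: float
    method: str
    binder_flag: str = "measured"

    def __post_init__(self):
        if self.ph not in (6.0, 7.0):
            raise CurationError(f"pH must be 6.0 or 7.0, got {self.ph}")
        if self.method not in VALID_METHODS:
            raise CurationError(f"unknown assay method {self.method!r}")
        if self.binder_flag == "measured" and (self.kd is None or self.kd <= 0):
            raise CurationError("measured record requires KD > 0")


@dataclasses.dataclass
class CuratedRecord:
    spec: VariantSpec
    signature: str
    log_kd: float          # log10 KD (M), harmonized to pH 7.0
    ph: float              # original assay pH
    method: str


@dataclasses.dataclass
class CuratedSet:
    set_id: str            # "FLS" or "SLS"
    records: list[CuratedRecord]
    removed_duplicates: int = 0
    removed_nonbinders: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def signatures(self) -> set[str]:
        return {r.signature for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "signature": [r.signature for r in self.records],
            "log_kd": [r.log_kd for r in self.records],
            "ph": [r.ph for r in self.records],
            "method": [r.method for r in self.records],
            "set_id": self.set_id,
        })


def harmonize_ph(record: VariantRecord,
                 factor: float | None = None) -> float:
    """log10 KD on the pH 7.0 scale.  pH 7.0 records pass through; for
    pH 6.0 records KD is multiplied by ``factor`` first.  Non-binders
    have no usable KD and raise :class:`CurationError`."""
    if record.binder_flag != "measured":
        raise CurationError("non-binder record has no harmonizable KD")
    if factor is None:
        factor = default_harmonization_factor()
    if factor <= 0:
        raise CurationError("harmonization factor must be positive")
    kd = record.kd if record.ph == 7.0 else record.kd * factor
    return math.log10(kd)


def effective_signature(spec: VariantSpec,
                        catalog_positions: Iterable[int]) -> str:
    """Canonical signature over catalog positions only.

    Mutations at off-catalog positions are invisible to the feature set
    and are dropped; an empty signature means wild-type-equivalent."""
    positions = frozenset(catalog_positions)
    kept = sorted(m for m in spec.mutations if m.eu_position in positions)
    return "/".join(str(m) for m in kept) if kept else "WT"


def deduplicate(records: Sequence[VariantRecord],
                catalog_positions: Iterable[int],
                set_id: str = "FLS",
                factor: float | None = None,
                conflict: str = "first") -> CuratedSet:
    """Harmonize, drop non-binders, and collapse effective-signature
    duplicates.  ``conflict`` is ``"first"`` (keep the first occurrence,
    the default) or ``"geometric_mean"`` (average duplicates in log
    space).  Input order is preserved; the result is deterministic."""
    if conflict not in ("first", "geometric_mean"):
        raise CurationError(f"unknown conflict policy {conflict!r}")
    positions = frozenset(catalog_positions)
    by_signature: dict[str, CuratedRecord] = {}
    dup_logs: dict[str, list[float]] = {}
    n_dup = 0
    n_nonbind = 0
    for rec in records:
        if rec.binder_flag != "measured":
            n_nonbind += 1
            continue
        log_kd = harmonize_ph(rec, factor)
        sig = effective_signature(rec.spec, positions)
        if sig in by_signature:
            n_dup += 1
            dup_logs[sig].append(log_kd)
            continue
        by_signature[sig] = CuratedRecord(rec.spec, sig, log_kd, rec.ph, rec.method)
        dup_logs[sig] = [log_kd]
    if conflict == "geometric_mean":
        for sig, cur in by_signature.items():
            cur.log_kd = sum(dup_logs[sig]) / len(dup_logs[sig])
    if n_nonbind:
        logger.info("excluded %d non-binder records", n_nonbind)
    if n_dup:
        logger.info("removed %d effective-signature duplicates", n_dup)
    return CuratedSet(set_id, list(by_signature.values()),
                      removed_duplicates=n_dup, removed_nonbinders=n_nonbind)


def build_learning_sets(records: Sequence[VariantRecord],
                        catalog_positions: Iterable[int],
                        factor: float | None = None,
                        conflict: str = "first") -> tuple[CuratedSet, CuratedSet]:
    """(FLS, SLS): FLS keeps pH 7.0 SPR records only; SLS adds the
    harmonized pH 6.0 records.  Both are deduplicated; SLS lists the
    FLS records first so signature collisions resolve to SPR data."""
    positions = frozenset(catalog_positions)
    fls_input = [r for r in records if r.ph == 7.0 and r.method == "SPR"]
    ph6_input = [r for r in records if r.ph == 6.0]
    if not fls_input:
        logger.warning("no pH 7.0 SPR records: FLS is empty")
    fls = deduplicate(fls_input, positions, "FLS", factor, conflict)
    sls = deduplicate(fls_input + ph6_input, positions, "SLS", factor, conflict)
    return fls, sls


# --- table I/O --------------------------------------------------------

def read_variant_table(source: str, sep: str = "\t") -> list[VariantRecord]:
    """Read a delimited variant table (path or literal text) with
    columns mutations / kd_molar / ph / method [/ binder_flag]."""
    try:
        df = pd.read_csv(source, sep=sep)
    except (OSError, FileNotFoundError):
        df = pd.read_csv(io.StringIO(source), sep=sep)
    required = {"mutations", "kd_molar", "ph", "method"}
    missing = required - set(df.columns)
    if missing:
        raise CurationError(f"variant table lacks columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        flag = getattr(row, "binder_flag", "measured")
        kd = None if pd.isna(row.kd_molar) else float(row.kd_molar)
        records.append(VariantRecord(
            spec=parse_mutations(str(row.mutations)),
            kd=kd, ph=float(row.ph), method=str(row.method),
            binder_flag=str(flag),
        ))
    return records


def write_variant_table(records: Sequence[VariantRecord], path: str,
                        sep: str = "\t") -> None:
    pd.DataFrame({
        "mutations": [str(r.spec) for r in records],
        "kd_molar": [r.kd for r in records],
        "ph": [r.ph for r in records],
        "method": [r.method for r in records],
        "binder_flag": [r.binder_flag for r in records],
    }).to_csv(path, sep=sep, index=False)
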