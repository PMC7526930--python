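"""Ingestion of the chrysanthemum transformation literature database.

The package ships a 49-study table of *Agrobacterium*-mediated
transformation experiments on chrysanthemum (GUS reporter scoring).  Each
study reports the bacterial strain(s), inoculum optical density (OD, with
the wavelength it was read at), co-culture period (CCP, days), doses of four
selection antibiotics (kanamycin K, hygromycin H, paromomycin P, geneticin
G; mg/L) and four counter-selection antibiotics (vancomycin VA, cefotaxime
CF, carbenicillin CA, ticarcillin TI; ug/mL), and the observed
transformation efficiency in percent.

Literature cells are messy: values may be ranges ("10-25"), antibiotics may
be absent ("-"), and a study may have used several strains.  This module
parses the raw cells, resolves them to single numeric rows under an explicit
policy, encodes the result as an 11-feature design matrix, and produces
seeded 70/20/10 train/test/validation splits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_NAMES",
    "ALLOWED_WAVELENGTHS",
    "TransformationRecord",
    "ResolutionPolicy",
    "EncodedDataset",
    "DataSplit",
    "ParseError",
    "EncodingError",
    "ConfigError",
    "fixture_path",
    "load_database",
    "resolve_records",
    "encode",
    "split",
]

#: Canonical order of the 11 model inputs (matches the study's factor list).
FEATURE_NAMES = ("strain", "OD", "CCP", "K", "H", "P", "G", "VA", "CF", "CA", "TI")

#: Wavelengths (nm) at which optical density was read in the source studies.
ALLOWED_WAVELENGTHS = frozenset({540, 550, 600, 660})

_ANTIBIOTIC_COLUMNS = (
    "kanamycin",
    "hygromycin",
    "paromomycin",
    "geneticin",
    "vancomycin",
    "cefotaxime",
    "carbenicillin",
    "ticarcillin",
)

# fixture column -> feature name
_COLUMN_TO_FEATURE = dict(
    zip(_ANTIBIOTIC_COLUMNS, ("K", "H", "P", "G", "VA", "CF", "CA", "TI"))
)


class ParseError(ValueError):
    """Raised when a fixture cell cannot be interpreted."""


class EncodingError(ValueError):
    """Raised when rows cannot be encoded (e.g. unseen strain at transform time)."""


class ConfigError(ValueError):
    """Raised for invalid policies / fractions."""


@dataclass(frozen=True)
class TransformationRecord:
    """One literature study, in raw units, before numeric resolution."""

    strains: tuple[str, ...]
    od_value: str
    od_wavelength_nm: int
    ccp_days: str | None
    kanamycin: str | None
    hygromycin: str | None
    paromomycin: str | None
    geneticin: str | None
    vancomycin: str | None
    cefotaxime: str | None
    carbenicillin: str | None
    ticarcillin: str | None
    efficiency_pct: str
    reference_id: str

    def __post_init__(self) -> None:
        if not self.strains:
            raise ParseError(f"{self.reference_id}: empty strain list")
        if self.od_wavelength_nm not in ALLOWED_WAVELENGTHS:
            raise ParseError(
                f"{self.reference_id}: OD wavelength {self.od_wavelength_nm} nm "
                f"not in {sorted(ALLOWED_WAVELENGTHS)}"
            )


@dataclass(frozen=True)
class ResolutionPolicy:
    """How raw literature cells become single numbers.

    range_policy
        'midpoint' (default), 'min' or 'max' for "a-b" cells.
    expand_strains
        one resolved row per strain in a multi-strain study (default) or
        keep only the first listed strain.
    """

    range_policy: Literal["midpoint", "min", "max"] = "midpoint"
    expand_strains: bool = True

    def resolve_range(self, lo: float, hi: float) -> float:
        if lo == hi:  # single value: return it exactly
            return lo
        if self.range_policy == "midpoint":
            return 0.5 * (lo + hi)
        if self.range_policy == "min":
            return lo
        if self.range_policy == "max":
            return hi
        raise ConfigError(f"unknown range policy {self.range_policy!r}")


@dataclass
class EncodedDataset:
    """Scaled n x 11 design matrix plus the metadata needed to invert it."""

    features: np.ndarray
    targets: np.ndarray
    feature_names: tuple[str, ...]
    strain_codebook: dict[str, int]
    scaling: dict[str, tuple[float, float]]
    provenance: np.ndarray  # source record index per row

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def unscale(self, features: np.ndarray) -> np.ndarray:
        """Map scaled features back to original units (inverse of min-max)."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        out = np.empty_like(features)
        for j, name in enumerate(self.feature_names):
            lo, hi = self.scaling[name]
            out[:, j] = features[:, j] * (hi - lo) + lo
        return out

    def scale(self, raw: np.ndarray) -> np.ndarray:
        """Min-max scale raw-unit features with the stored extrema."""
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        out = np.empty_like(raw)
        for j, name in enumerate(self.feature_names):
            lo, hi = self.scaling[name]
            span = hi - lo if hi > lo else 1.0
            out[:, j] = (raw[:, j] - lo) / span
        return out

    def metadata_json(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "strain_codebook": self.strain_codebook,
                "scaling": {k: list(v) for k, v in self.scaling.items()},
            },
            indent=2,
        )


@dataclass(frozen=True)
class DataSplit:
    train_idx: np.ndarray
    test_idx: np.ndarray
    val_idx: np.ndarray
    seed: int

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "training": self.train_idx,
            "testing": self.test_idx,
            "validation": self.val_idx,
        }


def fixture_path() -> Path:
    """Path of the packaged literature-table fixture."""
    return Path(resources.files("chrysopt").joinpath("data/table4.csv"))


def _parse_range(text: str, *, row: int, column: str) -> tuple[float, float]:
    """Parse '4.3', '4.3-13.4' (hyphen or en-dash), tolerating a trailing '%'."""
    cleaned = text.strip().replace("–", "-").rstrip("%").strip()
    # split on '-' that is not a leading sign
    parts = [p for p in cleaned.split("-") if p != ""]
    try:
        if len(parts) == 1:
            v = float(parts[0])
            lo = hi = v
        elif len(parts) == 2:
            lo, hi = float(parts[0]), float(parts[1])
        else:
            raise ValueError
    except ValueError:
        raise ParseError(f"row {row}, column {column!r}: cannot parse {text!r}") from None
    if lo < 0 or hi < lo:
        raise ParseError(f"row {row}, column {column!r}: bad range {text!r}")
    return lo, hi


def _cell(value: object) -> str | None:
    """Normalize a CSV cell: '-' or blank means absent."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if text in {"", "-", "–"}:
        return None
    return text


def load_database(path: str | Path | None = None) -> list[TransformationRecord]:
    """Load the literature table (the packaged fixture by default).

    Returns one :class:`TransformationRecord` per study row; absent
    antibiotic cells are preserved as ``None``; all numeric cells are
    validated (a malformed cell raises :class:`ParseError` naming the row
    and column).
    """
    path = fixture_path() if path is None else Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    records: list[TransformationRecord] = []
    for i, row in frame.iterrows():
        rownum = int(i) + 2  # 1-based + header, for error messages
        strains_cell = _cell(row["strains"])
        if strains_cell is None:
            raise ParseError(f"row {rownum}, column 'strains': empty")
        strains = tuple(s.strip() for s in strains_cell.split(";") if s.strip())
        od_value = _cell(row["od"])
        if od_value is None:
            raise ParseError(f"row {rownum}, column 'od': empty")
        _parse_range(od_value, row=rownum, column="od")
        try:
            wavelength = int(str(row["od_wavelength_nm"]).strip())
        except ValueError:
            raise ParseError(
                f"row {rownum}, column 'od_wavelength_nm': "
                f"cannot parse {row['od_wavelength_nm']!r}"
            ) from None
        if wavelength not in ALLOWED_WAVELENGTHS:
            raise ParseError(
                f"row {rownum}, column 'od_wavelength_nm': unknown wavelength {wavelength}"
            )
        ccp = _cell(row["ccp_days"])
        if ccp is not None:
            _parse_range(ccp, row=rownum, column="ccp_days")
        antibiotics = {}
        for col in _ANTIBIOTIC_COLUMNS:
            val = _cell(row[col])
            if val is not None:
                _parse_range(val, row=rownum, column=col)
            antibiotics[col] = val
        efficiency = _cell(row["efficiency_pct"])
        if efficiency is None:
            raise ParseError(f"row {rownum}, column 'efficiency_pct': empty")
        _parse_range(efficiency, row=rownum, column="efficiency_pct")
        records.append(
            TransformationRecord(
                strains=strains,
                od_value=od_value,
                od_wavelength_nm=wavelength,
                ccp_days=ccp,
                efficiency_pct=efficiency,
                reference_id=_cell(row["reference"]) or f"row{rownum}",
                **antibiotics,
            )
        )
    return records


def resolve_records(
    records: Sequence[TransformationRecord],
    policy: ResolutionPolicy = ResolutionPolicy(),
) -> pd.DataFrame:
    """Turn raw records into single-strain, single-number training rows.

    Ranges collapse under ``policy.range_policy`` (midpoint by default),
    multi-strain studies expand to one row per strain, absent antibiotics
    become dose 0.  A missing OD/CCP cell (one study has a blank CCP) is
    imputed with the column median over the studies that report it, since a
    zero duration/density would be physically meaningless.

    Returns a DataFrame with columns ``strain``, the ten numeric factors in
    canonical order, ``efficiency``, ``od_wavelength_nm`` (metadata, not a
    feature) and ``record_index`` (provenance).
    """

    def resolve_cell(text: str | None, *, row: int, column: str) -> float | None:
        if text is None:
            return None
        lo, hi = _parse_range(text, row=row, column=column)
        return policy.resolve_range(lo, hi)

    rows: list[dict] = []
    for idx, rec in enumerate(records):
        od = resolve_cell(rec.od_value, row=idx, column="od")
        ccp = resolve_cell(rec.ccp_days, row=idx, column="ccp_days")
        eff = resolve_cell(rec.efficiency_pct, row=idx, column="efficiency_pct")
        doses = {
            _COLUMN_TO_FEATURE[col]: resolve_cell(
                getattr(rec, col), row=idx, column=col
            )
            or 0.0
            for col in _ANTIBIOTIC_COLUMNS
        }
        strains = rec.strains if policy.expand_strains else rec.strains[:1]
        for strain in strains:
            rows.append(
                {
                    "strain": strain,
                    "OD": od,
                    "CCP": ccp,
                    **doses,
                    "efficiency": eff,
                    "od_wavelength_nm": rec.od_wavelength_nm,
                    "record_index": idx,
                }
            )
    frame = pd.DataFrame(rows)
    for col in ("OD", "CCP"):
        if frame[col].isna().any():
            frame[col] = frame[col].fillna(frame[col].median())
    return frame


def encode(
    rows: pd.DataFrame,
    *,
    strain_codebook: dict[str, int] | None = None,
    scaling: dict[str, tuple[float, float]] | None = None,
) -> EncodedDataset:
    """Encode resolved rows as a scaled n x 11 feature matrix.

    The strain is integer-coded in order of first appearance (so the model
    has exactly eleven inputs and sensitivity analysis ranks "strain" as one
    variable); all columns are then min-max scaled to [0, 1].  Pass an
    existing ``strain_codebook``/``scaling`` to encode new rows consistently
    with a previously encoded dataset.
    """
    if len(rows) == 0:
        raise EncodingError("no rows to encode")
    if strain_codebook is None:
        strain_codebook = {}
        for s in rows["strain"]:
            if s not in strain_codebook:
                strain_codebook[s] = len(strain_codebook)
    unseen = set(rows["strain"]) - set(strain_codebook)
    if unseen:
        raise EncodingError(f"unseen strain label(s): {sorted(unseen)}")

    raw = np.column_stack(
        [rows["strain"].map(strain_codebook).to_numpy(dtype=float)]
        + [rows[name].to_numpy(dtype=float) for name in FEATURE_NAMES[1:]]
    )
    if scaling is None:
        scaling = {}
        for j, name in enumerate(FEATURE_NAMES):
            lo, hi = float(raw[:, j].min()), float(raw[:, j].max())
            scaling[name] = (lo, hi)
    features = np.empty_like(raw)
    for j, name in enumerate(FEATURE_NAMES):
        lo, hi = scaling[name]
        span = hi - lo if hi > lo else 1.0
        features[:, j] = (raw[:, j] - lo) / span

    targets = rows["efficiency"].to_numpy(dtype=float)
    if np.any(~np.isfinite(targets)) or targets.min() < 0 or targets.max() > 100:
        raise EncodingError("efficiencies must be finite and within [0, 100]")
    provenance = (
        rows["record_index"].to_numpy()
        if "record_index" in rows
        else np.arange(len(rows))
    )
    return EncodedDataset(
        features=features,
        targets=targets,
        feature_names=FEATURE_NAMES,
        strain_codebook=dict(strain_codebook),
        scaling=dict(scaling),
        provenance=np.asarray(provenance),
    )


def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer split sizes by largest remainder; ties favour earlier entries
    (train > test > validation)."""
    exact = [f * n for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    remainder = n - sum(sizes)
    order = sorted(
        range(len(fractions)), key=lambda i: (-(exact[i] - sizes[i]), i)
    )
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def split(
    n_or_dataset: int | EncodedDataset,
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10),
    seed: int = 0,
) -> DataSplit:
    """Uniform random 70/20/10 partition (largest-remainder sizes, seeded)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"fractions {fractions} do not sum to 1")
    n = n_or_dataset if isinstance(n_or_dataset, int) else n_or_dataset.n
    if n < 10:
        raise ConfigError(f"need at least 10 rows to split, got {n}")
    sizes = _largest_remainder_sizes(n, fractions)
    perm = np.random.default_rng(seed).permutation(n)
    train = np.sort(perm[: sizes[0]])
    test = np.sort(perm[sizes[0] : sizes[0] + sizes[1]])
    val = np.sort(perm[sizes[0] + sizes[1] :])
    return DataSplit(train_idx=train, test_idx=test, val_idx=val, seed=seed)


def export_resolved(rows: pd.DataFrame, path: str | Path) -> None:
    """Write resolved rows as CSV (round-trips numerically)."""
    # shortest-repr floats; re-load exactly with float_precision="round_trip"
    rows.to_csv(path, index=False)


def dataset_bounds(rows: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Observed min-max of each factor in original units (default FOA bounds).

    The strain bound is over integer codes assigned by first appearance.
    """
    codes = {}
    for s in rows["strain"]:
        if s not in codes:
            codes[s] = len(codes)
    bounds = {"strain": (0.0, float(len(codes) - 1))}
    for name in FEATURE_NAMES[1:]:
        col = rows[name].to_numpy(dtype=float)
        bounds[name] = (float(col.min()), float(col.max()))
    return bounds
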