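"""Amino-acid physicochemical property tables backing the autocorrelation
(ACF) encoder.

A property table holds one numeric value per (property, residue) pair for
the 20 standard residues. The ACF encoder expects 531 properties, each
standardized to mean 0 and standard deviation 1 across the 20 residues.

Two sources are supported:

* :func:`load_aaindex` parses either the AAindex1 flat-file format
  (``H``/``I`` records separated by ``//``) or a TSV snapshot with one
  property per row and one column per residue.
* :func:`synthetic_aaindex_table` generates a deterministic *synthetic*
  stand-in table of the same shape for fully offline use. Its values are
  seeded random draws, not measured physicochemical scales; after
  standardization it exercises the ACF machinery identically, but individual
  descriptor values carry no biochemical meaning.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import ALPHABET, N_RESIDUES

N_PROPERTIES_DEFAULT = 531

# Residue order used by AAindex1 flat files (two rows of ten values each).
AAINDEX_FLAT_ORDER = "ARNDCQEGHILKMFPSTWYV"
_FLAT_TO_CANONICAL = [AAINDEX_FLAT_ORDER.index(aa) for aa in ALPHABET]


@dataclass(frozen=True)
class AAIndexTable:
    """Property values per residue, raw and standardized.

    ``raw`` and ``normalized`` are (n_properties, 20) arrays with columns in
    canonical alphabet order; each ``normalized`` row has mean 0 and
    population standard deviation 1 across the 20 residues.
    """

    property_ids: tuple[str, ...]
    raw: np.ndarray
    normalized: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.property_ids)
        if self.raw.shape != (n, N_RESIDUES) or self.normalized.shape != (n, N_RESIDUES):
            raise ValueError("property matrix shape does not match property_ids")

    @property
    def n_properties(self) -> int:
        return len(self.property_ids)


def standardize_rows(values: np.ndarray) -> np.ndarray:
    """Z-score each row across the 20 residues (population SD)."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a zero-variance property row")
    return (values - mean) / sd


def _process(
    ids: list[str], raw: np.ndarray, n_properties: int
) -> AAIndexTable:
    """Apply the fixed NA/variance policy and retain the first
    ``n_properties`` surviving rows in file order.

    Zero-variance rows (all available values equal) are excluded first, as
    they cannot be standardized. Then, if dropping every row containing a
    missing value still leaves at least ``n_properties`` rows, those rows
    are dropped; otherwise missing values are imputed with the property's
    mean over available residues.
    """
    with np.errstate(invalid="ignore"):
        variable = np.nanstd(raw, axis=1) > 0
    ids = [i for i, keep in zip(ids, variable) if keep]
    raw = raw[variable]

    has_na = np.isnan(raw).any(axis=1)
    if (~has_na).sum() >= n_properties:
        ids = [i for i, na in zip(ids, has_na) if not na]
        raw = raw[~has_na]
    else:
        row_means = np.nanmean(raw, axis=1)
        nan_r, nan_c = np.nonzero(np.isnan(raw))
        raw = raw.copy()
        raw[nan_r, nan_c] = row_means[nan_r]

    if len(ids) < n_properties:
        raise ValueError(
            f"only {len(ids)} usable properties, need {n_properties}"
        )
    ids = ids[:n_properties]
    raw = raw[:n_properties]
    return AAIndexTable(
        property_ids=tuple(ids), raw=raw, normalized=standardize_rows(raw)
    )


def _parse_flat(path: Path) -> tuple[list[str], np.ndarray]:
    ids: list[str] = []
    rows: list[list[float]] = []
    accession = None
    values: list[float] | None = None
    with open(path) as fh:
        lines = iter(fh)
        for line in lines:
            if line.startswith("H "):
                accession = line[2:].strip()
            elif line.startswith("I "):
                values = []
                for _ in range(2):
                    tokens = next(lines).split()
                    values.extend(
                        float("nan") if t.upper().startswith("NA") else float(t)
                        for t in tokens
                    )
            elif line.startswith("//"):
                if accession is None or values is None or len(values) != N_RESIDUES:
                    raise ValueError(
                        f"malformed AAindex record ending near {accession!r}"
                    )
                ids.append(accession)
                rows.append([values[k] for k in _FLAT_TO_CANONICAL])
                accession, values = None, None
    if not ids:
        raise ValueError(f"no AAindex records found in {path}")
    return ids, np.asarray(rows, dtype=np.float64)


def _parse_tsv(path: Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    missing = [aa for aa in ALPHABET if aa not in df.columns]
    if missing:
        raise ValueError(f"TSV snapshot lacks residue columns: {missing}")
    return list(df.index.astype(str)), df[list(ALPHABET)].to_numpy(dtype=np.float64)


def load_aaindex(
    path: str | Path, n_properties: int = N_PROPERTIES_DEFAULT
) -> AAIndexTable:
    """Load a property table from an AAindex1 flat file or a TSV snapshot.

    The format is sniffed from the first non-blank line: AAindex1 records
    start with a one-letter key (``H <accession>``); anything else is read
    as TSV (property id column + one column per residue letter).
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
    if first.startswith(("H ", "H\t")):
        ids, raw = _parse_flat(path)
    else:
        ids, raw = _parse_tsv(path)
    return _parse_result(ids, raw, n_properties)


def _parse_result(ids, raw, n_properties):
    return _process(ids, raw, n_properties)


def synthetic_aaindex_table(
    n_properties: int = N_PROPERTIES_DEFAULT, seed: int = 531
) -> AAIndexTable:
    """Deterministic **synthetic** property table.

    Values are standard-normal draws from a pinned generator — a stand-in of
    the right shape for the curated 531-property collection, not measured
    scales. Rows are standardized exactly like loaded tables.
    """
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_properties, N_RESIDUES))
    ids = [f"SYNTH{i + 1:04d}" for i in range(n_properties)]
    return _process(ids, raw, n_properties)


@lru_cache(maxsize=1)
def default_table() -> AAIndexTable:
    """The package-default 531-property table (synthetic, fixed seed)."""
    return synthetic_aaindex_table()


def write_tsv(table: AAIndexTable, path: str | Path) -> None:
    """Write the raw table as the TSV snapshot format read by load_aaindex."""
    df = pd.DataFrame(table.raw, index=list(table.property_ids), columns=list(ALPHABET))
    df.index.name = "property_id"
    df.to_csv(path, sep="\t")
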