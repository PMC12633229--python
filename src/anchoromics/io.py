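"""Data containers and file I/O for the anchored multi-omics pipeline.

Matrices are stored features-in-rows, samples-in-columns, log-scale values
with explicit missingness (NaN in memory, ``NA``/empty string on disk). All
identifiers are matched by string, never by position across files.

Also houses the targeted-proteomics (PRM-MS) peptide-to-protein rollup:
per-peptide median normalization, log2 transform, per-protein averaging.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("anchoromics")

MODALITIES = ("rna", "protein", "peptide", "metadata", "component")
GROUPS = ("Control", "MCI", "AD", "Other")

MISSING_TOKENS = ("", "NA")


class MatrixFormatError(ValueError):
    """Raised when a matrix/metadata/GMT file violates the format contract."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise MatrixFormatError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclasses.dataclass
class ExpressionMatrix:
    """A features x samples numeric matrix with a declared modality.

    ``values`` is a pandas DataFrame (rows = features, columns = samples);
    missing entries are NaN, never silently zero.
    """

    values: pd.DataFrame
    modality: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        _check_unique(list(self.values.index), "feature")
        _check_unique(list(self.values.columns), "sample")
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def feature(self, feature_id: str) -> pd.Series:
        """One feature's values across samples (a sample-indexed Series)."""
        if feature_id not in self.values.index:
            raise KeyError(f"feature {feature_id!r} not in matrix")
        return self.values.loc[feature_id]


@dataclasses.dataclass
class PeptidePanel:
    """Peptide-level raw peak areas plus a peptide -> protein map.

    Raw abundances are strictly positive where present (extracted-ion
    chromatogram peak areas); every peptide maps to exactly one protein.
    """

    abundance: pd.DataFrame  # peptides x samples, raw positive scale
    peptide_to_protein: dict[str, str]

    def __post_init__(self) -> None:
        _check_unique(list(self.abundance.index), "peptide")
        _check_unique(list(self.abundance.columns), "sample")
        missing_map = set(self.abundance.index) - set(self.peptide_to_protein)
        if missing_map:
            raise ValueError(
                f"peptides without protein mapping: {sorted(missing_map)[:5]}"
            )
        vals = self.abundance.to_numpy(float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("raw peptide abundances must be > 0 or missing")


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(members) != len(set(members)):
                raise ValueError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def read_matrix(path: str | Path, modality: str) -> ExpressionMatrix:
    """Read a tab-delimited matrix: first column feature ids, first row sample ids.

    Empty cells and the literal token ``NA`` are missing. Any other
    non-numeric cell is a hard error reporting its row/column coordinates.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, index_col=0)
    _check_unique(list(raw.index), "feature")
    _check_unique(list(raw.columns), "sample")
    parsed = raw.where(~raw.isin(MISSING_TOKENS))
    numeric = parsed.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & parsed.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise MatrixFormatError(
            f"non-numeric cell {raw.iat[r, c]!r} at feature {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r} in {path}"
        )
    # re-parse with Python's correctly-rounded float() so writes round-trip
    # bit-identically (pandas' fast parser is not round-trip exact)
    precise = parsed.apply(
        lambda col: col.map(lambda v: float(v) if isinstance(v, str) else np.nan)
    )
    return ExpressionMatrix(values=precise.astype(float), modality=modality)


def write_matrix(matrix: ExpressionMatrix | pd.DataFrame, path: str | Path) -> None:
    """Write a matrix as TSV with ``NA`` for missing; round-trips bit-identically."""
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    df.to_csv(Path(path), sep="\t", na_rep="NA", index_label="feature")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, group, age, sex, source, pmi, cerad, braak)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"])
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise MatrixFormatError("metadata must have 'sample_id' and 'group' columns")
    df = df.set_index("sample_id")
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    _check_unique(list(df.index), "sample")
    bad_groups = set(df["group"].dropna()) - set(GROUPS)
    if bad_groups:
        raise MatrixFormatError(f"unknown diagnosis group(s): {sorted(bad_groups)}")
    if df["group"].isna().any():
        raise MatrixFormatError("every sample needs a diagnosis group")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), sep="\t", na_rep="NA", index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: set name, description, tab-separated members.

    Members are deduplicated per set preserving first occurrence; a line with
    fewer than three fields is a hard error naming the line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MatrixFormatError(
                    f"GMT line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *members = fields
            if name in sets:
                raise MatrixFormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(m for m in members if m))
            if not deduped:
                raise MatrixFormatError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def rollup_peptides(panel: PeptidePanel) -> ExpressionMatrix:
    """Roll peptide peak areas up to protein-level log2 abundances.

    Each peptide is divided by its median over non-missing samples, log2
    transformed, and the transformed values of a protein's peptides are
    averaged per sample over non-missing entries. Peptides with no observed
    value (and proteins losing all their peptides) are dropped with a warning.
    """
    ab = panel.abundance
    transformed: dict[str, np.ndarray] = {}
    for pep in ab.index:
        row = ab.loc[pep].to_numpy(float)
        if not np.isfinite(row).any():
            logger.warning("peptide %s has no observed values; excluded from rollup", pep)
            continue
        med = float(np.nanmedian(row))
        transformed[pep] = np.log2(row / med)

    proteins: dict[str, list[str]] = {}
    for pep in transformed:
        proteins.setdefault(panel.peptide_to_protein[pep], []).append(pep)

    dropped = set(panel.peptide_to_protein.values()) - set(proteins)
    for prot in sorted(dropped):
        logger.warning("protein %s lost all peptides; excluded from rollup", prot)

    rows = {}
    for prot, peps in proteins.items():
        stack = np.vstack([transformed[p] for p in peps])
        with np.errstate(invalid="ignore"):
            rows[prot] = np.nanmean(stack, axis=0)
    out = pd.DataFrame(rows, index=ab.columns).T
    out = out.loc[sorted(rows)]
    return ExpressionMatrix(values=out, modality="protein")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: Mapping,
    seed: int,
    input_checksums: Mapping[str, str] | None = None,
) -> None:
    """Write a JSON run manifest: config echo, seed, versions, input checksums."""
    import anchoromics

    manifest = {
        "config": dict(config),
        "seed": int(seed),
        "versions": {
            "anchoromics": anchoromics.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "input_checksums": dict(input_checksums or {}),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
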