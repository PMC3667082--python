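"""Reading and writing expression matrices, gene lists, and sample manifests.

Expression matrices are represented as :class:`pandas.DataFrame` objects with
gene identifiers on the index (rows) and sample identifiers on the columns,
holding finite log2-scale expression values.  All text formats are UTF-8,
tab-delimited by default, with the identifier in the first column and a
header row of sample identifiers — the layout of level-3 style expression
tables.

This module also owns the two universe-level operations the downstream
statistics depend on: collapsing probe-level rows to gene-level rows by
averaging, and harmonizing gene universes across datasets by intersection.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "validate_expression",
    "collapse_probes",
    "harmonize_universe",
    "read_gene_list",
    "read_signature_file",
    "write_signature_file",
    "read_manifest",
    "write_manifest",
]


def validate_expression(expr: pd.DataFrame, *, allow_duplicate_ids: bool = False) -> pd.DataFrame:
    """Check the expression-matrix contract: unique non-empty string ids,
    finite float values.

    Returns the (possibly dtype-coerced) frame.  Raises ``ValueError`` on
    violation.  ``allow_duplicate_ids`` permits duplicated row ids, which is
    only legitimate for probe-level matrices awaiting :func:`collapse_probes`.
    """
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError("expression matrix must have at least one gene and one sample")
    if expr.columns.duplicated().any():
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    if not allow_duplicate_ids and expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(
            f"duplicate gene ids: {dups}; pass allow_duplicate_ids=True only if a "
            "probe-to-gene collapse follows"
        )
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        # locate the first offending cell for the error message
        for col in expr.columns:
            coerced = pd.to_numeric(expr[col], errors="coerce")
            bad = coerced.isna() & expr[col].notna()
            if bad.any():
                row = expr.index[bad.to_numpy().argmax()]
                raise ValueError(f"non-numeric value at gene {row!r}, sample {col!r}")
        expr = expr.astype(float)
        values = expr.to_numpy()
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite value at gene {expr.index[i]!r}, sample {expr.columns[j]!r}; "
            "missing entries are not permitted"
        )
    return expr.astype(float)


def read_expression_table(
    path: str | Path,
    *,
    delimiter: str = "\t",
    allow_duplicate_ids: bool = False,
) -> pd.DataFrame:
    """Read a tab-delimited expression table (first column ids, header row of
    sample ids) into a genes x samples DataFrame of finite floats."""
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split(delimiter)[1:]
    seen = pd.Index(header)
    if seen.duplicated().any():
        raise ValueError(f"duplicate sample ids: {seen[seen.duplicated()].unique().tolist()}")
    frame = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    frame.index = frame.index.astype(str).rename(None)
    frame.columns = frame.columns.astype(str)
    try:
        frame = frame.apply(pd.to_numeric)
    except (ValueError, TypeError):
        pass  # validate_expression reports the offending cell
    return validate_expression(frame, allow_duplicate_ids=allow_duplicate_ids)


def write_expression_table(expr: pd.DataFrame, path: str | Path, *, delimiter: str = "\t") -> None:
    """Write an expression matrix in the same format read_expression_table reads.

    Values are written at full repr precision so that a write/read round trip
    is exact.
    """
    expr.to_csv(path, sep=delimiter, index_label="gene_id")


def collapse_probes(expr: pd.DataFrame, probe_map: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level by averaging probe rows.

    Each gene's row is the unweighted arithmetic mean of the rows of all its
    probes (on the log2 scale).  Probes absent from ``probe_map`` are dropped
    with a logged count; an empty intersection of probes and map is an error.
    Gene rows are returned in lexicographic order.
    """
    mapping = pd.Series(dict(probe_map) if not isinstance(probe_map, pd.Series) else probe_map)
    present = expr.index.intersection(mapping.index)
    n_unmapped = expr.shape[0] - len(present)
    if len(present) == 0:
        raise ValueError("no probe in the matrix is present in the probe map")
    if n_unmapped:
        logger.info("collapse_probes: dropping %d unmapped probe rows", n_unmapped)
    sub = expr.loc[present]
    genes = mapping.loc[present]
    collapsed = sub.groupby(genes.to_numpy()).mean()
    collapsed.index.name = expr.index.name
    return collapsed.sort_index()


def harmonize_universe(*universes: Iterable[str]) -> frozenset[str]:
    """Intersect two or more gene universes into a shared background set.

    The result is the set of genes measured in every dataset — the sampling
    frame for overlap testing.  Commutative and associative; an empty
    intersection is an error.
    """
    sets = [frozenset(u) for u in universes]
    if len(sets) < 2:
        raise ValueError("harmonize_universe needs at least two universes")
    if any(len(s) == 0 for s in sets):
        raise ValueError("harmonize_universe: empty input universe")
    shared = frozenset.intersection(*sets)
    if not shared:
        raise ValueError("harmonized universe is empty: the datasets share no genes")
    logger.info("harmonize_universe: %d shared genes from %d universes", len(shared), len(sets))
    return shared


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and ``#`` comment lines ignored."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_signature_file(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a plain-text signature file with ``#up`` / ``#down`` section markers."""
    up: list[str] = []
    down: list[str] = []
    current: list[str] | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("#"):
            if low == "#up":
                current = up
            elif low == "#down":
                current = down
            continue
        if current is None:
            raise ValueError(f"{path}: gene id {line!r} before any #up/#down section marker")
        current.append(line)
    return up, down


def write_signature_file(path: str | Path, up: Iterable[str], down: Iterable[str]) -> None:
    lines = ["#up", *sorted(up), "#down", *sorted(down), ""]
    Path(path).write_text("\n".join(lines))


def read_manifest(path: str | Path, *, delimiter: str = "\t") -> pd.Series:
    """Read a sample manifest (columns: sample_id, group) into a Series
    mapping sample id to group label."""
    frame = pd.read_csv(path, sep=delimiter, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: manifest needs at least two columns (sample_id, group)")
    sample_col, group_col = frame.columns[:2]
    if frame[sample_col].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in manifest")
    return pd.Series(frame[group_col].to_numpy(), index=frame[sample_col], name="group")


def write_manifest(groups: pd.Series, path: str | Path, *, delimiter: str = "\t") -> None:
    frame = pd.DataFrame({"sample_id": groups.index, "group": groups.to_numpy()})
    frame.to_csv(path, sep=delimiter, index=False)


def frame_to_json(frame: pd.DataFrame, path: str | Path) -> None:
    """Mirror a TSV export as JSON (records orientation)."""
    Path(path).write_text(json.dumps(frame.reset_index().to_dict(orient="records"), indent=1))
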