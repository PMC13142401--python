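"""Readers and writers for every tabular format the pipeline touches.

All tables are UTF-8, tab- or comma-separated by extension (decimal point,
never comma).  Readers validate headers and invariants and fail loudly;
every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger("thermobgc.io")

#: The six biosynthetic class labels used throughout the pipeline.
BGC_CLASSES = ("NRPS", "PKS", "RiPP", "terpene", "hybrid", "other")

_CLASS_LOOKUP = {c.lower(): c for c in BGC_CLASSES}

#: Reference (MIBiG-like) node ids are recognised by accession pattern.
REFERENCE_ID_PATTERN = r"^BGC\d{7}"

_METADATA_COLUMNS = [
    "sample_id",
    "temperature",
    "pH",
    "conductivity",
    "crustal_thickness",
    "sequencing_depth",
    "tectonic_setting",
    "volcanic_province",
]

_CONTIG_COLUMNS = ["contig_id", "sample_id", "contig_length", "genus", "support"]


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def is_reference_id(bgc_id: str, pattern: str = REFERENCE_ID_PATTERN) -> bool:
    """True when *bgc_id* matches the reference-accession pattern."""
    return re.match(pattern, bgc_id) is not None


@dataclass(frozen=True)
class NetworkDialect:
    """Column layout of a pairwise-distance network file.

    The default mimics BiG-SCAPE ``.network`` output: tab-separated, the two
    node ids in the first two columns and a raw-distance column named
    ``Raw distance``.  ``NetworkDialect.minimal()`` accepts any 3+ column
    file positionally.
    """

    node_a: str = "Clustername 1"
    node_b: str = "Clustername 2"
    distance: str = "Raw distance"
    positional: bool = False

    @classmethod
    def minimal(cls) -> "NetworkDialect":
        return cls(positional=True)


def read_network(path: str | Path, dialect: NetworkDialect | None = None) -> pd.DataFrame:
    """Read a pairwise BGC distance network into an edge-list frame.

    Returns a frame with columns ``bgc_a, bgc_b, distance``.  Self-loops are
    dropped; duplicate (unordered) pairs are collapsed keeping the minimum
    distance; any distance outside [0, 1] raises, naming the offending row.
    """
    path = Path(path)
    dialect = dialect or NetworkDialect()
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if dialect.positional:
        if raw.shape[1] < 3:
            raise ValueError(f"{path}: minimal network dialect needs >= 3 columns")
        cols = list(raw.columns[:3])
    else:
        cols = []
        for fname, col in (("node_a", dialect.node_a), ("node_b", dialect.node_b), ("distance", dialect.distance)):
            if col not in raw.columns:
                raise ValueError(f"{path}: missing column {col!r} required by dialect field {fname!r}")
            cols.append(col)
    edges = raw[cols].copy()
    edges.columns = ["bgc_a", "bgc_b", "distance"]
    edges["distance"] = pd.to_numeric(edges["distance"], errors="raise")
    bad = edges.index[(edges["distance"] < 0) | (edges["distance"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: distance outside [0, 1] at row {bad[0] + 2} (1-based incl. header)")
    edges = edges[edges["bgc_a"] != edges["bgc_b"]]
    key = edges[["bgc_a", "bgc_b"]].apply(lambda r: tuple(sorted(r)), axis=1) if len(edges) else pd.Series(dtype=object)
    edges = edges.assign(_key=key)
    edges = edges.sort_values("distance", kind="stable").drop_duplicates("_key", keep="first")
    edges = edges.drop(columns="_key").sort_values(["bgc_a", "bgc_b"], kind="stable").reset_index(drop=True)
    return edges


def write_network(path: str | Path, edges: pd.DataFrame, dialect: NetworkDialect | None = None) -> None:
    """Write an edge list in the dialect's column layout (canonical order)."""
    dialect = dialect or NetworkDialect()
    out = edges[["bgc_a", "bgc_b", "distance"]].copy()
    if not dialect.positional:
        out.columns = [dialect.node_a, dialect.node_b, dialect.distance]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_inventory(path: str | Path) -> pd.DataFrame:
    """Read a per-sample BGC inventory (bgc_id, sample_id, bgc_class).

    Class labels are normalised case-insensitively onto the six allowed
    labels; anything unrecognised maps to ``other`` with a counted warning.
    Duplicate bgc_id is an error.  An empty file yields an empty frame.
    """
    path = Path(path)
    inv = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    required = ["bgc_id", "sample_id", "bgc_class"]
    missing = [c for c in required if c not in inv.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    dup = inv["bgc_id"][inv["bgc_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate bgc_id {dup.iloc[0]!r}")
    unknown = 0
    norm = []
    for label in inv["bgc_class"]:
        canon = _CLASS_LOOKUP.get(str(label).strip().lower())
        if canon is None:
            unknown += 1
            canon = "other"
        norm.append(canon)
    if unknown:
        logger.warning("%s: %d unrecognised class labels mapped to 'other'", path, unknown)
    inv = inv[required].copy()
    inv["bgc_class"] = norm
    inv["is_reference"] = [is_reference_id(b) for b in inv["bgc_id"]]
    return inv.reset_index(drop=True)


def write_inventory(path: str | Path, inventory: pd.DataFrame) -> None:
    inventory[["bgc_id", "sample_id", "bgc_class"]].to_csv(path, sep=_sep_for(Path(path)), index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample environmental metadata (CSV), indexed by sample_id.

    Enforces: unique sample ids, pH in [0, 14], sequencing_depth >= 0.
    """
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in _METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id")
    if ((meta["pH"] < 0) | (meta["pH"] > 14)).any():
        raise ValueError(f"{path}: pH outside [0, 14]")
    if (meta["sequencing_depth"] < 0).any():
        raise ValueError(f"{path}: negative sequencing_depth")
    return meta.set_index("sample_id")


def write_metadata(path: str | Path, meta: pd.DataFrame) -> None:
    out = meta.reset_index() if meta.index.name == "sample_id" else meta
    out[_METADATA_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_contigs(path: str | Path) -> pd.DataFrame:
    """Read a CAT-style contig classification table (TSV)."""
    path = Path(path)
    tab = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in _CONTIG_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if (tab["contig_length"] <= 0).any():
        raise ValueError(f"{path}: non-positive contig_length")
    if ((tab["support"] < 0) | (tab["support"] > 1)).any():
        raise ValueError(f"{path}: support outside [0, 1]")
    return tab[_CONTIG_COLUMNS].reset_index(drop=True)


def write_contigs(path: str | Path, contigs: pd.DataFrame) -> None:
    contigs[_CONTIG_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    """Write a samples x features matrix as TSV (sample rows)."""
    out = matrix.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def config_digest(config: Mapping) -> str:
    """Stable SHA-256 digest of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_results_json(
    path: str | Path,
    results: Mapping,
    *,
    seed: int,
    config: Mapping | None = None,
) -> None:
    """Serialise results with full provenance (seed, config hash, version)."""
    from thermobgc import __version__

    payload = {
        "provenance": {
            "seed": int(seed),
            "config_sha256": config_digest(config or {}),
            "version": __version__,
        },
        "results": results,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")


def read_results_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
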