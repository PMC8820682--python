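"""Shared data model and file I/O for the miRNA analysis pipeline.

All downstream stages consume the containers defined here (:class:`CountMatrix`,
:class:`ExpressionMatrix`, :class:`QpcrTable`, :class:`Signature`); no stage
re-reads raw files.  Tables are plain tab-delimited text; signatures use the
GMT dialect (one set per line: name, description, then member ids).
"""

from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hepamir")

SAMPLE_COLUMNS = ("sample_id", "diet", "time_h", "treatment", "replicate")

_PREFIX_RE = re.compile(r"^(?P<species>[a-z]{3}-)?(?P<stem>mir|let)(?P<rest>.*)$", re.IGNORECASE)

#: Curated aliases resolving typographical variants seen in the source tables
#: (e.g. a dropped hyphen before the arm suffix).  Applied after prefix
#: normalization; unresolved ids are reported by callers, never dropped.
DEFAULT_ALIASES: Mapping[str, str] = {
    "miR-3405p": "miR-340-5p",
}


def normalize_mirna_id(mirna_id: str, aliases: Mapping[str, str] | None = DEFAULT_ALIASES) -> str:
    """Canonicalize a miRNA id: trim whitespace, case-fold the miR/let prefix.

    Matching across tables is exact-string on the canonical form; only the
    "miR"/"let" stem (and any 3-letter species prefix) is case-folded, the
    numeric part and arm suffix are left untouched so that e.g. miR-143 and
    miR-143-3p remain distinct.
    """
    s = mirna_id.strip()
    m = _PREFIX_RE.match(s)
    if m:
        species = (m.group("species") or "").lower()
        stem = "miR" if m.group("stem").lower() == "mir" else "let"
        s = f"{species}{stem}{m.group('rest')}"
    if aliases and s in aliases:
        s = aliases[s]
    return s


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-metadata contract and return a normalized copy."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing required columns: {missing}")
    out = samples.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    if out["sample_id"].duplicated().any():
        dups = sorted(out.loc[out["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicate sample ids: {dups}")
    out["time_h"] = pd.to_numeric(out["time_h"])
    if (out["time_h"] < 0).any():
        raise ValueError("time_h must be >= 0")
    out["replicate"] = out["replicate"].astype(int)
    if (out["replicate"] < 1).any():
        raise ValueError("replicate index must be >= 1")
    key = out[["diet", "time_h", "treatment", "replicate"]]
    if key.duplicated().any():
        raise ValueError("duplicate (diet, time_h, treatment, replicate) tuples")
    return out.reset_index(drop=True)


@dataclass
class CountMatrix:
    """miRNA-by-sample nonnegative integer counts with sample metadata.

    ``counts``: DataFrame, index = miRNA ids, columns = sample ids.
    ``samples``: metadata table with one row per sample (see SAMPLE_COLUMNS).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = validate_sample_table(self.samples)
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate miRNA ids in count matrix")
        matrix_ids = list(self.counts.columns.astype(str))
        meta_ids = list(self.samples["sample_id"])
        only_matrix = sorted(set(matrix_ids) - set(meta_ids))
        only_meta = sorted(set(meta_ids) - set(matrix_ids))
        if only_matrix or only_meta:
            raise ValueError(
                "sample ids do not reconcile between counts and metadata: "
                f"only in matrix {only_matrix}, only in metadata {only_meta}"
            )
        # normalize column order to metadata order
        self.counts = self.counts.loc[:, meta_ids]
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"count matrix cell at miRNA {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r} is not a nonnegative integer "
                f"(value {arr[i, j]!r})"
            )
        self.counts = self.counts.astype(np.int64)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def cpm(self) -> pd.DataFrame:
        """Raw counts-per-million (no scaling factors, no log)."""
        return self.counts / self.library_sizes.to_numpy() * 1e6

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        keep = self.samples[self.samples["sample_id"].isin(set(sample_ids))]
        return CountMatrix(self.counts.loc[:, list(keep["sample_id"])], keep)

    def subset_mirnas(self, mirna_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(mirna_ids)], self.samples)


@dataclass
class ExpressionMatrix:
    """log2-cpm expression values, optionally with positive precision weights."""

    values: pd.DataFrame
    samples: pd.DataFrame
    weights: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.samples = validate_sample_table(self.samples)
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if self.weights is not None:
            w = self.weights.to_numpy()
            if w.shape != self.values.shape:
                raise ValueError("weights shape differs from values shape")
            if not (np.isfinite(w).all() and (w > 0).all()):
                raise ValueError("weights must be positive and finite")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        keep = self.samples[self.samples["sample_id"].isin(set(sample_ids))]
        ids = list(keep["sample_id"])
        w = self.weights.loc[:, ids] if self.weights is not None else None
        return ExpressionMatrix(self.values.loc[:, ids], keep, w)


@dataclass(frozen=True)
class Signature:
    """A named miRNA set with cell-type and direction labels."""

    name: str
    members: tuple[str, ...]
    cell_type: str = "other"
    direction: str = "enriched"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"signature {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"signature {self.name!r} has duplicate members")


def validate_qpcr_table(table: pd.DataFrame) -> pd.DataFrame:
    required = ("group", "target", "replicate", "ct")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    out = table.copy()
    out["ct"] = pd.to_numeric(out["ct"])
    if not np.isfinite(out["ct"].to_numpy()).all():
        raise ValueError("CT values must be finite")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> pd.DataFrame:
    return validate_sample_table(pd.read_csv(path, sep="\t"))


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    validate_sample_table(samples).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a tab-delimited count matrix (rows = miRNAs) plus its metadata.

    Samples are reconciled by id and reordered to metadata order; any id on
    one side only, or any non-integer/negative cell, is rejected with a
    message naming the offender.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    samples = read_sample_table(metadata_path)
    return CountMatrix(counts, samples)


def write_counts(cm: CountMatrix, counts_path: str | Path, metadata_path: str | Path | None = None) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="mirna_id")
    if metadata_path is not None:
        write_sample_table(cm.samples, metadata_path)


def read_expression(path: str | Path, metadata_path: str | Path,
                    weights_path: str | Path | None = None) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    samples = read_sample_table(metadata_path)
    values = values.loc[:, list(samples["sample_id"])]
    weights = None
    if weights_path is not None:
        weights = pd.read_csv(weights_path, sep="\t", index_col=0).loc[values.index, values.columns]
    return ExpressionMatrix(values, samples, weights)


def write_expression(em: ExpressionMatrix, path: str | Path,
                     weights_path: str | Path | None = None) -> None:
    em.values.to_csv(path, sep="\t", index_label="mirna_id", float_format="%.12g")
    if weights_path is not None and em.weights is not None:
        em.weights.to_csv(weights_path, sep="\t", index_label="mirna_id", float_format="%.12g")


def read_qpcr(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return validate_qpcr_table(pd.read_csv(path, sep=sep))


def write_qpcr(table: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    validate_qpcr_table(table).to_csv(path, sep=sep, index=False, float_format="%.12g")


def _parse_description(desc: str) -> tuple[str, str]:
    cell_type, direction = "other", "enriched"
    for part in desc.split(";"):
        part = part.strip()
        if part.startswith("cell_type="):
            cell_type = part.split("=", 1)[1]
        elif part.startswith("direction="):
            d = part.split("=", 1)[1]
            if d in {"up", "down", "enriched"}:
                direction = d
    return cell_type, direction


def read_signatures(path: str | Path, aliases: Mapping[str, str] | None = DEFAULT_ALIASES) -> list[Signature]:
    """Parse a GMT file into signatures, de-duplicating members in order."""
    sigs: list[Signature] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 tab-separated fields")
            name, desc, raw_members = fields[0], fields[1], fields[2:]
            if name in names:
                raise ValueError(f"{path}: duplicate signature name {name!r}")
            names.add(name)
            members: list[str] = []
            for m in raw_members:
                mid = normalize_mirna_id(m, aliases)
                if mid and mid not in members:
                    members.append(mid)
            cell_type, direction = _parse_description(desc)
            sigs.append(Signature(name, tuple(members), cell_type, direction))
    if not sigs:
        logger.warning("signature file %s is empty", path)
    return sigs


def write_signatures(sigs: Iterable[Signature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in sigs:
            desc = f"cell_type={sig.cell_type};direction={sig.direction}"
            fh.write("\t".join([sig.name, desc, *sig.members]) + "\n")


def read_panel(path: str | Path) -> list[str]:
    """Read a one-id-per-line miRNA panel, skipping '#' comments."""
    with open(path) as fh:
        return [normalize_mirna_id(line) for line in fh
                if line.strip() and not line.startswith("#")]


def load_packaged_signatures() -> list[Signature]:
    """Nonparenchymal cell-type signatures (HSC up/down, LSEC, KC) shipped with the package."""
    ref = importlib.resources.files("hepamir") / "data" / "cell_type_signatures.gmt"
    with importlib.resources.as_file(ref) as p:
        return read_signatures(p)


def load_packaged_panel() -> list[str]:
    """Synthetic pseudo-panel: the signature members known to overlap the study's bulk data."""
    ref = importlib.resources.files("hepamir") / "data" / "pseudo_bulk_panel.txt"
    with importlib.resources.as_file(ref) as p:
        return read_panel(p)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_expressed(counts: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3) -> CountMatrix:
    """Keep miRNAs with cpm >= ``min_cpm`` in at least ``min_samples`` samples.

    Order is preserved; an empty result is returned with a warning rather
    than raised.
    """
    if min_cpm < 0:
        raise ValueError("min_cpm must be >= 0")
    n = len(counts.sample_ids)
    if not 0 <= min_samples <= n:
        raise ValueError(f"min_samples must be in [0, {n}]")
    keep = (counts.cpm() >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        logger.warning("expression filter removed every miRNA")
    return CountMatrix(counts.counts.loc[keep], counts.samples)
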