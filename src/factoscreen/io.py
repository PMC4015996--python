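"""Reading and writing count screens.

Two plain-text dialects are supported:

``rcc_like``
    A single CSV file of per-sample blocks.  Each block starts with a
    header line ``Sample,<sample_id>,lane,<lane>`` followed by one
    ``<Class>,<Symbol>,<Count>`` line per probe, with class codes
    ``Endogenous``, ``Housekeeping``, ``Positive`` and ``Negative``.

``tsv``
    A genes x samples count table (first column ``symbol``) with a
    sidecar gene-annotation TSV (``symbol``, ``cls``, ``marker_set``).

Sample annotations (condition, donor, day) travel in a design TSV in
either dialect.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, ValidationError
from .design import GenePanel

__all__ = ["read_counts", "write_counts", "read_design", "write_design",
           "ParseError"]

_CLASS_CODES = {
    "Endogenous": "endogenous",
    "Housekeeping": "housekeeping_candidate",
    "Positive": "positive_ctrl",
    "Negative": "negative_ctrl",
}
_CODES_BY_CLASS = {v: k for k, v in _CLASS_CODES.items()}


class ParseError(ValueError):
    """File does not parse under the declared dialect."""


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index_label="sample_id")


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", index_col="sample_id")
    return design


def write_counts(cm: CountMatrix, path, dialect: str = "rcc_like",
                 annotation_path=None) -> None:
    """Serialize a count matrix; the ``tsv`` dialect also writes the gene
    annotation sidecar (default ``<path>.genes.tsv``)."""
    path = Path(path)
    if dialect == "rcc_like":
        with open(path, "w") as fh:
            for sid in cm.values.columns:
                lane = int(cm.samples.loc[sid, "lane"]) if "lane" in cm.samples else 0
                fh.write(f"Sample,{sid},lane,{lane}\n")
                for sym in cm.values.index:
                    code = _CODES_BY_CLASS[cm.genes.loc[sym, "cls"]]
                    fh.write(f"{code},{sym},{int(cm.values.at[sym, sid])}\n")
    elif dialect == "tsv":
        cm.values.to_csv(path, sep="\t", index_label="symbol")
        ann = Path(annotation_path) if annotation_path else path.with_suffix(
            path.suffix + ".genes.tsv")
        cm.genes.to_csv(ann, sep="\t", index_label="symbol")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _parse_count(raw: str, sym: str, sid: str) -> int:
    try:
        val = float(raw)
    except ValueError:
        raise ValidationError(
            f"non-numeric count {raw!r} for gene {sym!r} in sample {sid!r}"
        ) from None
    if val < 0:
        raise ValidationError(
            f"negative count {val} for gene {sym!r} in sample {sid!r}")
    if val != int(val):
        raise ValidationError(
            f"non-integer count {val} for gene {sym!r} in sample {sid!r}")
    return int(val)


def read_counts(path, dialect: str = "rcc_like",
                design: pd.DataFrame | None = None,
                panel: GenePanel | None = None,
                annotation_path=None) -> CountMatrix:
    """Read a count matrix.

    Gene class labels come from the file (``rcc_like``), the sidecar
    annotation TSV (``tsv``) or an explicit panel; sample annotations
    come from ``design`` (falling back to lane-only metadata for
    ``rcc_like`` files read without one).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "rcc_like":
        return _read_rcc_like(path, design, panel)
    if dialect == "tsv":
        return _read_tsv(path, design, panel, annotation_path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_rcc_like(path: Path, design, panel) -> CountMatrix:
    per_sample: dict[str, dict[str, int]] = {}
    lanes: dict[str, int] = {}
    classes: dict[str, str] = {}
    order: list[str] = []
    sid = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if parts[0] == "Sample":
                if len(parts) != 4 or parts[2] != "lane":
                    raise ParseError(f"{path}:{lineno}: malformed sample header")
                sid = parts[1]
                per_sample[sid] = {}
                lanes[sid] = int(parts[3])
            else:
                if sid is None:
                    raise ParseError(f"{path}:{lineno}: counts before any sample header")
                if len(parts) != 3:
                    raise ParseError(f"{path}:{lineno}: expected class,symbol,count")
                code, sym, raw = parts
                if code not in _CLASS_CODES:
                    raise ParseError(
                        f"{path}:{lineno}: unknown gene class code {code!r}")
                per_sample[sid][sym] = _parse_count(raw, sym, sid)
                if sym not in classes:
                    classes[sym] = _CLASS_CODES[code]
                    order.append(sym)
    if not per_sample:
        raise ParseError(f"{path}: no sample blocks found")
    values = pd.DataFrame({s: pd.Series(d) for s, d in per_sample.items()})
    values = values.loc[order]
    values.index.name = "symbol"
    if values.isna().any().any():
        raise ParseError(f"{path}: inconsistent probe sets across samples")
    values = values.astype(np.int64)
    if panel is not None:
        genes = panel.genes.loc[values.index]
    else:
        genes = pd.DataFrame({"cls": pd.Series(classes)})
        genes["marker_set"] = "other"
        genes.index.name = "symbol"
        genes = genes.loc[values.index]
    if design is not None:
        samples = design.loc[values.columns]
    else:
        samples = pd.DataFrame({"lane": pd.Series(lanes)})
        samples.index.name = "sample_id"
        samples["condition_id"] = -1
        samples["donor"] = -1
        samples["day"] = -1
        samples = samples.loc[values.columns]
    return CountMatrix(values, genes, samples)


def _read_tsv(path: Path, design, panel, annotation_path) -> CountMatrix:
    values = pd.read_csv(path, sep="\t", index_col="symbol")
    arr = values.to_numpy()
    bad = ~np.isfinite(arr) | (arr < 0) | (arr != np.rint(arr))
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValidationError(
            f"invalid count {arr[g, s]!r} for gene {values.index[g]!r} in "
            f"sample {values.columns[s]!r}")
    values = values.astype(np.int64)
    if panel is not None:
        genes = panel.genes.loc[values.index]
    else:
        ann = Path(annotation_path) if annotation_path else path.with_suffix(
            path.suffix + ".genes.tsv")
        if not ann.exists():
            raise ParseError(f"gene annotation sidecar not found: {ann}")
        genes = pd.read_csv(ann, sep="\t", index_col="symbol").loc[values.index]
        unknown = set(genes["cls"]) - set(_CODES_BY_CLASS)
        if unknown:
            raise ParseError(f"unknown gene class code {sorted(unknown)[0]!r}")
    if design is not None:
        samples = design.loc[values.columns]
    else:
        samples = pd.DataFrame(index=values.columns)
        samples.index.name = "sample_id"
        samples["condition_id"] = -1
        samples["donor"] = -1
        samples["day"] = -1
        samples["lane"] = np.arange(1, len(values.columns) + 1)
    return CountMatrix(values, genes, samples)
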