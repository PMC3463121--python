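"""File formats: TSV matrices, module/CV/truth JSON documents."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from . import __version__
from .blocks import OmicsBlock
from .estimators import ExtractionResult
from .exceptions import DegenerateInputError, ParameterError
from .modules import MDRM
from .simulate import SimulationTruth
from .tuning import CVResult

PathLike = Union[str, Path]

SCHEMA_VERSION = "1"


def read_block(path: PathLike, name: str) -> OmicsBlock:
    """Parse a tab-separated matrix: variable-ID header, sample-ID first column.

    Validation errors name the offending row/column label.
    """
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas raises many flavors on ragged/bad input
        raise ParameterError(f"cannot parse {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ParameterError(f"{path}: duplicate sample id {dup!r}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ParameterError(f"{path}: duplicate variable id {dup!r}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~frame.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParameterError(
            f"{path}: non-numeric value at sample {frame.index[r]!r}, "
            f"variable {frame.columns[c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParameterError(
            f"{path}: missing value at sample {frame.index[r]!r}, "
            f"variable {frame.columns[c]!r} (ragged row?)"
        )
    try:
        return OmicsBlock.from_frame(numeric, name)
    except DegenerateInputError as exc:
        raise ParameterError(f"{path}: {exc}") from exc


def write_block(block: OmicsBlock, path: PathLike) -> None:
    block.to_frame().to_csv(path, sep="\t")


def load_schema() -> dict:
    with resources.files("smbpls.schemas").joinpath("modules.schema.json").open() as fh:
        return json.load(fh)


_JSON_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "boolean": bool,
}


def _check_schema(doc, schema: dict, where: str = "$") -> None:
    """Minimal structural validation: type, required, enum, minItems, items."""
    expected = schema.get("type")
    if expected and not isinstance(doc, _JSON_TYPES[expected]):
        raise ParameterError(f"{where}: expected {expected}")
    if "enum" in schema and doc not in schema["enum"]:
        raise ParameterError(f"{where}: {doc!r} not in {schema['enum']}")
    if expected == "object":
        for key in schema.get("required", []):
            if key not in doc:
                raise ParameterError(f"{where}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in doc:
                _check_schema(doc[key], sub, f"{where}.{key}")
    if expected == "array":
        if len(doc) < schema.get("minItems", 0):
            raise ParameterError(f"{where}: fewer than {schema['minItems']} items")
        items = schema.get("items")
        if items:
            for i, item in enumerate(doc):
                _check_schema(item, items, f"{where}[{i}]")


def validate_modules_document(doc: dict) -> None:
    """Validate a module document against the shipped schema."""
    _check_schema(doc, load_schema())


def modules_document(result: ExtractionResult) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "tool": "smbpls",
        "tool_version": __version__,
        "stop_reason": result.stop_reason,
        "modules": [m.to_dict() for m in result.modules],
    }


def write_modules(result: ExtractionResult, path: PathLike) -> None:
    """Serialize an extraction result as a versioned JSON document."""
    if not result.modules:
        raise ParameterError("refusing to serialize an empty extraction result")
    doc = modules_document(result)
    validate_modules_document(doc)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_modules(path: PathLike) -> tuple[list[MDRM], dict]:
    """Load modules plus document metadata; validates against the schema."""
    doc = json.loads(Path(path).read_text())
    validate_modules_document(doc)
    meta = {k: v for k, v in doc.items() if k != "modules"}
    return [MDRM.from_dict(m) for m in doc["modules"]], meta


def write_truth(truth: SimulationTruth, path: PathLike) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True) + "\n")


def read_truth(path: PathLike) -> SimulationTruth:
    return SimulationTruth.from_dict(json.loads(Path(path).read_text()))


def write_cv_result(result: CVResult, path: PathLike) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=1, sort_keys=True) + "\n")
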