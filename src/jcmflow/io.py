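"""Reading and writing single-cell expression data and fitted models.

Supports FCS 3.0/3.1 list-mode float data (the output of modern
instruments after compensation and scale transformation), plain CSV/TSV
matrices with a marker-name header, JSON model documents, and per-cell
label files (one integer per line, 0 = outlier/unassigned, 1..g =
registered population index).

No compensation or intensity transformation is applied on read: samples
are assumed to be preprocessed, and any arcsinh transform is an explicit
caller decision (see the CLI's ``--arcsinh`` flag).
"""

from __future__ import annotations

import csv
import json
import struct
from dataclasses import dataclass, field

import numpy as np

from .distributions import ComponentParams, MixtureModel

__all__ = [
    "FormatError",
    "MarkerSample",
    "SampleBatch",
    "read_fcs",
    "write_fcs",
    "read_csv_matrix",
    "write_csv_matrix",
    "save_model",
    "load_model",
    "write_labels",
    "read_labels",
]

SCHEMA_VERSION = "1.0"


class FormatError(ValueError):
    """Raised when a file does not conform to its declared format."""


@dataclass
class MarkerSample:
    """One sample: an (n_cells, n_markers) expression matrix plus metadata."""

    sample_id: str
    marker_names: list[str]
    data: np.ndarray
    class_label: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_markers(self) -> int:
        return self.data.shape[1]

    def validate(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("data must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("expression matrix contains non-finite values")
        if len(self.marker_names) != self.data.shape[1]:
            raise ValueError("marker_names length does not match column count")
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("marker_names are not unique")

    def select_markers(self, markers: list[str]) -> "MarkerSample":
        missing = [m for m in markers if m not in self.marker_names]
        if missing:
            raise KeyError(
                f"markers {missing} not present; available: {self.marker_names}")
        idx = [self.marker_names.index(m) for m in markers]
        return MarkerSample(self.sample_id, list(markers), self.data[:, idx],
                            self.class_label, self.condition)


@dataclass
class SampleBatch:
    """A class/batch of samples sharing an identical marker panel."""

    class_id: str
    samples: list[MarkerSample] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.samples)

    @property
    def marker_names(self) -> list[str]:
        return self.samples[0].marker_names

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("batch must contain at least one sample")
        names = self.samples[0].marker_names
        for s in self.samples:
            s.validate()
            if s.marker_names != names:
                raise ValueError(
                    f"sample {s.sample_id!r} markers {s.marker_names} differ from {names}")


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    parts = raw.decode("latin-1").split(delim)[1:]
    if len(parts) % 2 == 1:
        parts = parts[:-1]
    return {parts[i].strip(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path, markers: list[str] | None = None) -> MarkerSample:
    """Read an FCS 3.0/3.1 list-mode float file into a MarkerSample.

    Only $DATATYPE F (float32) and D (float64) with $MODE L are supported;
    integer data and FCS 2.0 files are rejected.  ``markers`` restricts and
    orders the returned columns by $PnN name.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    version = raw[:6].decode("latin-1", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"unsupported FCS version {version!r} (need FCS3.0/FCS3.1)")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
        data_start = int(raw[26:34])
        data_end = int(raw[34:42])
    except ValueError as exc:
        raise FormatError("malformed FCS header offsets") from exc
    text = _parse_text_segment(raw[text_start:text_end + 1])
    if data_start == 0 or data_end == 0:
        data_start = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))
    datatype = text.get("$DATATYPE", "?")
    if datatype not in ("F", "D"):
        raise FormatError(f"unsupported $DATATYPE {datatype!r} (need F or D)")
    mode = text.get("$MODE", "?")
    if mode != "L":
        raise FormatError(f"unsupported $MODE {mode!r} (need L, list mode)")
    byteord = text.get("$BYTEORD", "")
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FormatError(f"unsupported $BYTEORD {byteord!r}")
    par = int(text["$PAR"])
    tot = int(text["$TOT"])
    names = []
    for i in range(1, par + 1):
        names.append(text.get(f"$P{i}N", f"P{i}"))
        bits = int(text.get(f"$P{i}B", 32 if datatype == "F" else 64))
        expect = 32 if datatype == "F" else 64
        if bits != expect:
            raise FormatError(f"$P{i}B={bits} inconsistent with $DATATYPE {datatype}")
    dtype = np.dtype(endian + ("f4" if datatype == "F" else "f8"))
    nbytes = tot * par * dtype.itemsize
    seg = raw[data_start:data_start + nbytes]
    if len(seg) < nbytes:
        raise FormatError("DATA segment shorter than $TOT x $PAR events")
    data = np.frombuffer(seg, dtype=dtype).reshape(tot, par).astype(float)
    sample = MarkerSample(sample_id=str(path), marker_names=names, data=data)
    if markers is not None:
        sample = sample.select_markers(list(markers))
    sample.validate()
    return sample


def write_fcs(path, sample: MarkerSample, datatype: str = "D") -> None:
    """Write a MarkerSample as a minimal FCS 3.1 list-mode float file.

    Intended for simulation export and round-trip testing, not as an
    instrument-grade writer.
    """
    if datatype not in ("F", "D"):
        raise ValueError("datatype must be 'F' or 'D'")
    sample.validate()
    n, p = sample.data.shape
    bits = 32 if datatype == "F" else 64
    kv = {
        "$DATATYPE": datatype, "$MODE": "L", "$BYTEORD": "1,2,3,4",
        "$PAR": str(p), "$TOT": str(n), "$NEXTDATA": "0",
    }
    for i, name in enumerate(sample.marker_names, start=1):
        kv[f"$P{i}N"] = name
        kv[f"$P{i}B"] = str(bits)
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = "262144"
    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kv.items()) + delim
    header_len = 58
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + n * p * (bits // 8) - 1
    header = (b"FCS3.1    "
              + f"{text_start:>8d}{text_end:>8d}{data_start:>8d}{data_end:>8d}"
                f"{0:>8d}{0:>8d}".encode("ascii"))
    assert len(header) == header_len
    arr = sample.data.astype("<f4" if datatype == "F" else "<f8")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("latin-1"))
        fh.write(arr.tobytes())


# ---------------------------------------------------------------------------
# CSV / TSV


def read_csv_matrix(path, has_header: bool = True) -> MarkerSample:
    """Read a rectangular numeric CSV/TSV table as a MarkerSample.

    The delimiter (comma or tab) is inferred from the first line.  A
    non-numeric cell raises a FormatError reporting its 1-based (row,
    column) position within the data block.
    """
    with open(path, "r", newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty file")
        delim = "\t" if first.count("\t") >= first.count(",") else ","
        fh.seek(0)
        rows = [r for r in csv.reader(fh, delimiter=delim) if any(c.strip() for c in r)]
    if has_header:
        names = [c.strip() for c in rows[0]]
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path}: no data rows")
    ncol = len(rows[0])
    if not has_header:
        names = [f"V{i+1}" for i in range(ncol)]
    data = np.empty((len(rows), ncol))
    for i, row in enumerate(rows):
        if len(row) != ncol:
            raise FormatError(f"{path}: ragged row {i + 1} has {len(row)} fields, expected {ncol}")
        for j, cell in enumerate(row):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {cell!r} at ({i + 1}, {j + 1})") from None
    sample = MarkerSample(sample_id=str(path), marker_names=names, data=data)
    sample.validate()
    return sample


def write_csv_matrix(path, sample: MarkerSample) -> None:
    """Write a MarkerSample as a comma-separated table with a header row."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(sample.marker_names)
        for row in sample.data:
            wr.writerow([repr(float(v)) for v in row])


# ---------------------------------------------------------------------------
# JSON model documents


def _component_to_dict(c: ComponentParams) -> dict:
    return {"pi": c.pi, "mu": c.mu.tolist(), "Sigma": c.Sigma.tolist(),
            "delta": c.delta.tolist(), "nu": c.nu}


def _component_from_dict(d: dict) -> ComponentParams:
    return ComponentParams(pi=d["pi"], mu=np.array(d["mu"]),
                           Sigma=np.array(d["Sigma"]),
                           delta=np.array(d["delta"]), nu=d["nu"])


def _mixture_to_dict(model: MixtureModel) -> dict:
    return {
        "family": model.family,
        "g": model.g,
        "p": model.p,
        "marker_names": list(model.marker_names),
        "components": [_component_to_dict(c) for c in model.components],
    }


def _mixture_from_dict(d: dict) -> MixtureModel:
    model = MixtureModel(family=d["family"],
                         components=[_component_from_dict(c) for c in d["components"]],
                         marker_names=list(d.get("marker_names", [])))
    model.validate()
    return model


def save_model(model, path) -> None:
    """Serialize a MixtureModel or JCMFit to a self-describing JSON document."""
    from .jcm import JCMFit  # local import: jcm builds on this module's types

    if isinstance(model, MixtureModel):
        model.validate()
        doc = {"schema": SCHEMA_VERSION, "kind": "mixture", **_mixture_to_dict(model)}
    elif isinstance(model, JCMFit):
        doc = {"schema": SCHEMA_VERSION, "kind": "jcm", **model.to_dict()}
    else:
        raise TypeError(f"cannot serialize object of type {type(model).__name__}")
    text = json.dumps(doc, indent=1, sort_keys=True)
    if "NaN" in text:
        raise ValueError("model contains NaN parameters; refusing to serialize")
    with open(path, "w") as fh:
        fh.write(text)


def load_model(path):
    """Deserialize a JSON model document written by :func:`save_model`."""
    from .jcm import JCMFit

    with open(path) as fh:
        doc = json.load(fh)
    schema = doc.get("schema")
    if schema != SCHEMA_VERSION:
        raise FormatError(f"unsupported model schema {schema!r} (expected {SCHEMA_VERSION!r})")
    kind = doc.get("kind")
    if kind == "mixture":
        return _mixture_from_dict(doc)
    if kind == "jcm":
        return JCMFit.from_dict(doc, _mixture_from_dict)
    raise FormatError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# label files


def write_labels(path, labels: np.ndarray, component_names: list[str] | None = None) -> None:
    """Write per-cell labels, one integer per line (0 = outlier/unassigned).

    A sidecar ``<path>.components`` names the registered template
    components so label h can be traced back to population h.
    """
    labels = np.asarray(labels, dtype=int)
    with open(path, "w") as fh:
        fh.write("\n".join(str(v) for v in labels) + "\n")
    if component_names:
        with open(f"{path}.components", "w") as fh:
            for i, name in enumerate(component_names, start=1):
                fh.write(f"{i}\t{name}\n")


def read_labels(path) -> np.ndarray:
    with open(path) as fh:
        return np.array([int(line) for line in fh if line.strip()], dtype=int)
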