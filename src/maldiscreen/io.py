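"""Reading and writing of spectra, plate maps, and feature tables.

Formats
-------
Spectra are exchanged either as two-column tab-separated text (m/z, intensity;
profile mode) or as mzML.  mzML support is a compact built-in reader/writer
pair (64-bit little-endian arrays; the reader also accepts 32-bit and
zlib-compressed payloads) that round-trips bit-exactly.

Plate maps and feature tables are plain CSV (UTF-8, comma separated, header
required, ``.`` decimal).  Readers validate and refuse malformed input rather
than coercing it; writers round-trip losslessly.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .errors import (
    MissingControlError,
    ParseError,
    PlateMapError,
    SpectrumValidationError,
)

DEFAULT_MASS_RANGE = (2000.0, 20000.0)

ROLES = frozenset(
    {"test", "positive_control", "negative_control", "vehicle", "stimulated"}
)

#: Accepted spellings for well roles in external plate-map CSVs.
ROLE_ALIASES = {
    "pos": "positive_control",
    "pos_ctrl": "positive_control",
    "positive": "positive_control",
    "poscontrol": "positive_control",
    "neg": "negative_control",
    "neg_ctrl": "negative_control",
    "negative": "negative_control",
    "negcontrol": "negative_control",
    "veh": "vehicle",
    "dmso": "vehicle",
    "stim": "stimulated",
    "sample": "test",
    "compound": "test",
}

PLATE_MAP_COLUMNS = [
    "plate",
    "well",
    "role",
    "compound",
    "concentration",
    "set",
    "technical_replicate",
    "biological_replicate",
]

FEATURE_TABLE_COLUMNS = [
    "plate",
    "well",
    "role",
    "compound",
    "set",
    "technical_replicate",
    "biological_replicate",
    "area_4632",
    "area_4964",
    "area_6891",
    "raw_ratio",
    "normalized_ratio",
    "percent_effect",
    "flags",
]


@dataclass
class Spectrum:
    """One MALDI-TOF profile: m/z axis, intensities and acquisition metadata.

    Invariants enforced at construction: strictly increasing m/z, equal array
    lengths, finite intensities.
    """

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumValidationError("mz and intensity must be 1-D arrays")
        if len(self.mz) != len(self.intensity):
            raise SpectrumValidationError(
                f"length mismatch: {len(self.mz)} m/z vs {len(self.intensity)} intensities"
            )
        if len(self.mz) == 0:
            raise SpectrumValidationError("empty spectrum")
        if not np.all(np.diff(self.mz) > 0):
            raise SpectrumValidationError("m/z axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise SpectrumValidationError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.mz)

    def copy_with(self, intensity: np.ndarray, **meta) -> "Spectrum":
        md = dict(self.metadata)
        md.update(meta)
        return Spectrum(self.mz.copy(), np.asarray(intensity, dtype=float), md)


@dataclass
class WellRecord:
    """One plate-map row: where a well is and what was in it."""

    plate: str
    well: str
    role: str
    compound: str | None = None
    concentration: float | None = None
    set: str | None = None
    technical_replicate: int = 1
    biological_replicate: int = 1

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PlateMapError(f"unknown role {self.role!r} for well {self.well!r}")
        if self.role in ("positive_control", "negative_control") and self.compound:
            raise PlateMapError(
                f"control well {self.well!r} must not carry a test-compound id"
            )
        if self.concentration is not None and self.concentration < 0:
            raise PlateMapError(f"negative concentration for well {self.well!r}")


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def _flag_out_of_range(spec: Spectrum, mass_range) -> Spectrum:
    low, high = mass_range
    n_out = int(np.count_nonzero((spec.mz < low) | (spec.mz > high)))
    if n_out:
        spec.metadata["out_of_range_points"] = n_out
    return spec


def read_spectrum_txt(path, mass_range=DEFAULT_MASS_RANGE) -> Spectrum:
    """Read a two-column (m/z TAB intensity) text spectrum.

    Points outside ``mass_range`` are retained but counted in
    ``metadata['out_of_range_points']``.
    """
    path = Path(path)
    mz, inten = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                mz.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not mz:
        raise ParseError(f"{path}: no data rows")
    spec = Spectrum(np.array(mz), np.array(inten), {"source": str(path), "format": "txt"})
    return _flag_out_of_range(spec, mass_range)


def write_spectrum_txt(spectrum: Spectrum, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{float(m)!r}\t{float(i)!r}\n")


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, values).

    Understands the common encodings: 64-/32-bit float, zlib or no
    compression.  Kind is 'mz', 'intensity' or None for other arrays.
    """
    dtype, compressed, kind, payload = "<f8", False, None, ""
    for child in bda.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif name == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path, mass_range=DEFAULT_MASS_RANGE) -> list[Spectrum]:
    """Read all spectra from an mzML file.

    Uses a small namespace-agnostic parser over the mzML schema (the
    environment ships no standalone mzML reader); supports the profile-mode
    encodings this package and the common converters write.
    """
    import xml.etree.ElementTree as ET

    path = Path(path)
    out = []
    try:
        for _, elem in ET.iterparse(str(path)):
            if _localname(elem.tag) != "spectrum":
                continue
            arrays: dict[str, np.ndarray] = {}
            title = None
            for sub in elem.iter():
                name = _localname(sub.tag)
                if name == "binaryDataArray":
                    kind, values = _decode_binary_array(sub)
                    if kind:
                        arrays[kind] = values
                elif name == "cvParam" and sub.get("accession") == "MS:1000796":
                    title = sub.get("value")
            if "mz" not in arrays or "intensity" not in arrays:
                raise ParseError(
                    f"{path}: spectrum {elem.get('id')!r} lacks m/z or intensity array"
                )
            meta = {"source": str(path), "format": "mzML", "scan_id": elem.get("id")}
            if title:
                meta["title"] = title
            out.append(
                _flag_out_of_range(Spectrum(arrays["mz"], arrays["intensity"], meta), mass_range)
            )
            elem.clear()
    except SpectrumValidationError:
        raise
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: malformed mzML ({exc})") from exc
    if not out:
        raise ParseError(f"{path}: no spectra found")
    return out


def read_spectrum(path, format: str | None = None, mass_range=DEFAULT_MASS_RANGE) -> Spectrum:
    """Read a single spectrum; format inferred from the extension if not given."""
    path = Path(path)
    if format is None:
        format = "mzML" if path.suffix.lower() == ".mzml" else "txt"
    if format.lower() == "mzml":
        return read_mzml(path, mass_range)[0]
    if format == "txt":
        return read_spectrum_txt(path, mass_range)
    raise ParseError(f"unknown spectrum format {format!r}")


def _encode_array(values: np.ndarray) -> str:
    raw = np.asarray(values, dtype="<f8").tobytes()
    return base64.b64encode(raw).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="maldiscreen" version="0.1.0"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="maldiscreen">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="run1" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{count}" defaultDataProcessingRef="DP1">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="{sid}" defaultArrayLength="{npts}">
        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>{title}
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{lmz}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{bmz}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{lint}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{bint}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(spectra, path) -> None:
    """Write profile-mode spectra to mzML (uncompressed 64-bit arrays).

    The output is intentionally minimal but schema-conformant enough for
    standard readers; round-tripping through :func:`read_mzml` preserves the
    arrays bit-exactly.
    """
    if isinstance(spectra, Spectrum):
        spectra = [spectra]
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to write")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MZML_HEADER.format(count=len(spectra)))
        for i, spec in enumerate(spectra):
            bmz = _encode_array(spec.mz)
            bint = _encode_array(spec.intensity)
            well = spec.metadata.get("well")
            title = ""
            if well is not None:
                title = (
                    '\n        <cvParam cvRef="MS" accession="MS:1000796" '
                    f'name="spectrum title" value="{escape(str(well))}"/>'
                )
            sid = escape(str(spec.metadata.get("scan_id") or f"scan={i + 1}"))
            fh.write(
                _MZML_SPECTRUM.format(
                    index=i,
                    sid=sid,
                    npts=len(spec),
                    title=title,
                    lmz=len(bmz),
                    bmz=bmz,
                    lint=len(bint),
                    bint=bint,
                )
            )
        fh.write(_MZML_FOOTER)


def write_spectrum(spectrum: Spectrum, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "mzML" if path.suffix.lower() == ".mzml" else "txt"
    if format.lower() == "mzml":
        write_mzml([spectrum], path)
    elif format == "txt":
        write_spectrum_txt(spectrum, path)
    else:
        raise ValueError(f"unknown spectrum format {format!r}")


# ---------------------------------------------------------------------------
# plate maps
# ---------------------------------------------------------------------------


def normalize_role(role: str) -> str:
    key = str(role).strip().lower()
    key = ROLE_ALIASES.get(key, key)
    if key not in ROLES:
        raise PlateMapError(f"unknown role label {role!r}")
    return key


def read_plate_map(path) -> pd.DataFrame:
    """Read and validate a plate-map CSV.

    Required columns: plate, well, role, compound, concentration, set,
    technical_replicate, biological_replicate.  Role aliases such as
    ``pos_ctrl`` are normalized; duplicate (plate, well, technical_replicate,
    biological_replicate) keys and unknown roles are rejected.
    """
    df = pd.read_csv(path, dtype={"plate": str, "well": str, "set": str, "compound": str})
    missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise PlateMapError(f"{path}: missing column(s) {missing}")
    df = df.copy()
    df["role"] = df["role"].map(normalize_role)
    key = ["plate", "well", "technical_replicate", "biological_replicate"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise PlateMapError(f"{path}: duplicate plate-map key {first}")
    ctrl = df["role"].isin(["positive_control", "negative_control"])
    bad = ctrl & df["compound"].notna() & (df["compound"].astype(str) != "")
    if bad.any():
        raise PlateMapError(
            f"{path}: control wells carry test-compound ids: "
            f"{df.loc[bad, 'well'].unique().tolist()}"
        )
    if (df["concentration"].fillna(0) < 0).any():
        raise PlateMapError(f"{path}: negative concentration")
    return df


def write_plate_map(platemap: pd.DataFrame, path) -> None:
    platemap.to_csv(path, index=False, columns=PLATE_MAP_COLUMNS)


def check_plate_controls(platemap: pd.DataFrame) -> None:
    """Refuse plate maps in which some compound set lacks a control.

    Every (plate, set) group must contain at least one positive and one
    negative control well; raises :class:`MissingControlError` naming the
    offenders otherwise.
    """
    offenders = []
    for (plate, set_id), grp in platemap.groupby(["plate", "set"], dropna=False):
        roles = set(grp["role"])
        if "positive_control" not in roles or "negative_control" not in roles:
            offenders.append((plate, set_id))
    if offenders:
        raise MissingControlError(
            f"set(s) lacking positive/negative controls: {offenders}"
        )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


def write_feature_table(quants, path) -> None:
    """Write per-well feature quantifications to CSV.

    ``quants`` is a DataFrame (or list of mappings) with the documented
    columns; floats are serialized with ``repr`` so the table re-reads to full
    precision.  NaN percent effect (control wells) becomes an empty field.
    """
    if not isinstance(quants, pd.DataFrame):
        quants = pd.DataFrame([q.__dict__ if hasattr(q, "__dict__") else q for q in quants])
    if quants.empty:
        raise ValueError("refusing to write an empty feature table")
    cols = [c for c in FEATURE_TABLE_COLUMNS if c in quants.columns]
    cols += [c for c in quants.columns if c not in cols]
    quants.to_csv(path, index=False, columns=cols, float_format=lambda x: repr(float(x)))


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"plate": str, "well": str, "set": str, "compound": str},
        float_precision="round_trip",
    )
    if df.empty:
        raise ParseError(f"{path}: empty feature table")
    if "flags" in df.columns:
        df["flags"] = df["flags"].fillna("")
    return df
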