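"""The dual-mode library: units tying nanodot bitmaps to DNA files.

A library is a grid of storage units.  Unit 0 holds the catalog (a
nanodot bitmap listing every other unit's name and grid position).
Each remaining unit pairs a concise bitmap — a short description plus
the PCR primer pair of the paired archival file — with the DNA strands
of that file.  Random access follows the catalog to a unit, reads the
primers from its concise bitmap (through the AFM imaging channel),
amplifies/sequences the unit's strands in silico, and runs the read
decoder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as dio
from .afm_image import DotModel, plane_flatten, read_matrix, synthesize_image
from .channel_sim import ChannelParams, simulate_reads
from .concise_codec import (
    BitMatrix,
    CatalogRecord,
    decode_catalog,
    decode_concise_file,
    encode_catalog,
    encode_concise_file,
)
from .detailed_codec import (
    DEFAULT_LAYOUT,
    PrimerPair,
    SequenceLayout,
    StrandRecord,
    design_primer_pairs,
    encode_file,
)
from .read_decode import DecodeReport, recover_file

__all__ = [
    "StorageUnit",
    "DualModeLibrary",
    "build_demo_library",
    "random_access",
    "demo_payload",
    "save_library",
    "load_library",
]

_WORDS = (
    "archive storage nanodot array substrate strand primer record unit data "
    "lattice surface probe height image index catalog concise detailed file "
    "access read write density stability decade century molecule sequence"
).split()


def _demo_text(rng: np.random.Generator, n_bytes: int) -> str:
    """Deterministic pseudo-random ASCII prose of exactly n_bytes bytes."""
    words = []
    size = 0
    while size < n_bytes:
        w = _WORDS[int(rng.integers(len(_WORDS)))]
        words.append(w)
        size += len(w) + 1
    text = " ".join(words)[: n_bytes - 1] + "."
    return text


def demo_payload(seed: int = 0) -> bytes:
    """The 1,999-byte demonstration payload: 404 bytes of text followed
    by 1,595 bytes of (pseudo-random) image data."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 404, 1595])
    text = _demo_text(rng, 404).encode("ascii")
    image = rng.integers(0, 256, size=1595, dtype=np.uint8).tobytes()
    assert len(text) == 404
    return text + image


@dataclass
class StorageUnit:
    unit_id: int
    name: str
    row: int
    col: int
    concise_matrix: BitMatrix
    primer_pair: PrimerPair
    strands: list[StrandRecord] = field(default_factory=list)
    detailed_payload: bytes = b""

    @property
    def n_strands(self) -> int:
        return len(self.strands)


@dataclass
class DualModeLibrary:
    catalog: BitMatrix
    units: list[StorageUnit]
    layout: SequenceLayout = DEFAULT_LAYOUT

    def unit_by_name(self, name: str) -> StorageUnit:
        for u in self.units:
            if u.name == name:
                return u
        raise KeyError(f"file {name!r} not in catalog")


# unit 0 is the catalog; data units fill the rest of a 2x3 grid
_GRID_POSITIONS = [(0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (1, 2)]
_DEMO_FILES = [
    # (name, detailed payload size in bytes, payload kind)
    ("seal", 1595, "image"),
    ("name", 404, "text"),
    ("motto", 260, "text"),
    ("anthem", 620, "text"),
    ("ethos", 180, "text"),
]


def build_demo_library(
    seed: int = 0, layout: SequenceLayout = DEFAULT_LAYOUT
) -> DualModeLibrary:
    """Deterministic six-unit demo library: one catalog plus five units,
    each pairing a concise description with an encoded detailed file.

    The detailed payloads include one 404-byte text file and one
    1,595-byte binary (image-like) file.
    """
    pairs = design_primer_pairs(len(_DEMO_FILES), seed=seed)
    units = []
    records = []
    for i, (name, size, kind) in enumerate(_DEMO_FILES):
        unit_id = i + 1
        row, col = _GRID_POSITIONS[unit_id]
        rng = np.random.default_rng([seed & 0x7FFFFFFF, unit_id])
        if kind == "text":
            payload = _demo_text(rng, size).encode("ascii")
        else:
            payload = rng.integers(0, 256, size=size, dtype=np.uint8).tobytes()
        pair = pairs[i]
        strands = encode_file(payload, file_id=unit_id, primer_pair=pair,
                              layout=layout, seed=seed)
        body = f"{name}: " + _demo_text(rng, 60)
        concise = encode_concise_file(body, pair.forward, pair.reverse)
        units.append(
            StorageUnit(unit_id, name, row, col, concise, pair, strands, payload)
        )
        records.append(CatalogRecord(unit_id, name, row, col))
    catalog = encode_catalog(records)
    return DualModeLibrary(catalog=catalog, units=units, layout=layout)


def _matrix_via_afm(
    m: BitMatrix, dot: DotModel, seed: Optional[int]
) -> BitMatrix:
    """Round-trip a bit matrix through the AFM imaging channel.

    The array is written with a fiducial border of 1-dots so the grid
    extent is detectable even when edge rows of the payload (e.g. the
    leading zeros of the length header) carry no dots; the border is
    stripped after read-out.
    """
    framed = BitMatrix(np.pad(m.bits, 1, constant_values=1))
    img = synthesize_image(framed, dot, seed=seed)
    out = read_matrix(plane_flatten(img))
    bits = out.bits
    if bits.shape[0] < 3 or bits.shape[1] < 3:
        raise ValueError("AFM read-out lost the fiducial border")
    return BitMatrix(bits[1:-1, 1:-1], pitch_nm=dot.pitch_nm)


def random_access(
    library: DualModeLibrary,
    target_name: str,
    channel: ChannelParams = ChannelParams(),
    seed: Optional[int] = None,
    dot: DotModel = DotModel(),
    via_afm: bool = True,
) -> tuple[bytes, DecodeReport]:
    """Retrieve one detailed file through the full in-silico read path.

    Catalog bitmap -> (AFM image round trip) -> unit position -> concise
    bitmap -> primer pair -> simulated sequencing of that unit's strands
    -> read decoding.  ``via_afm=False`` skips the imaging channel and
    reads the bitmaps directly.
    """
    cat = _matrix_via_afm(library.catalog, dot, seed) if via_afm else library.catalog
    records = decode_catalog(cat)
    rec = next((r for r in records if r.file_name == target_name), None)
    if rec is None:
        raise KeyError(f"file {target_name!r} not in catalog")
    unit = next(
        u for u in library.units
        if (u.row, u.col) == (rec.row, rec.col) and u.unit_id == rec.unit_id
    )
    cm = _matrix_via_afm(unit.concise_matrix, dot, seed) if via_afm else unit.concise_matrix
    concise = decode_concise_file(cm)
    pair = PrimerPair(concise.forward_primer, concise.reverse_primer)
    reads = simulate_reads([s.full for s in unit.strands], channel, seed=seed)
    return recover_file(reads, pair, unit.n_strands, library.layout)


# --------------------------------------------------------------------------
# on-disk form: manifest.json + per-unit FASTA + matrix TSV


def save_library(library: DualModeLibrary, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {"layout": library.layout.to_config(), "units": []}
    dio.write_matrix_tsv(d / "catalog.tsv", library.catalog)
    for u in library.units:
        dio.write_matrix_tsv(d / f"unit{u.unit_id}_concise.tsv", u.concise_matrix)
        dio.write_fasta(
            d / f"unit{u.unit_id}_strands.fasta",
            [(f"{u.unit_id}:{s.index}", s.full) for s in u.strands],
        )
        manifest["units"].append(
            {
                "unit_id": u.unit_id,
                "name": u.name,
                "row": u.row,
                "col": u.col,
                "n_strands": u.n_strands,
                "forward_primer": u.primer_pair.forward,
                "reverse_primer": u.primer_pair.reverse,
            }
        )
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_library(directory) -> DualModeLibrary:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    layout = SequenceLayout(**manifest["layout"])
    catalog = dio.read_matrix_tsv(d / "catalog.tsv")
    units = []
    for mu in manifest["units"]:
        uid = mu["unit_id"]
        concise = dio.read_matrix_tsv(d / f"unit{uid}_concise.tsv")
        pair = PrimerPair(mu["forward_primer"], mu["reverse_primer"])
        strands = []
        for rid, seq in dio.read_fasta(d / f"unit{uid}_strands.fasta"):
            _, idx = rid.split(":")
            strands.append(
                StrandRecord(file_id=uid, index=int(idx), mod_primer_a="",
                             mod_primer_b="", seed="", core="", full=seq)
            )
        units.append(
            StorageUnit(uid, mu["name"], mu["row"], mu["col"], concise, pair, strands)
        )
    return DualModeLibrary(catalog=catalog, units=units, layout=layout)
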