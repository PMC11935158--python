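"""Standard-format I/O: FASTA/FASTQ (gzip-transparent), bit-matrix TSV
and image files, height-map TSV/PGM/PNG, and flat key-value configs."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from PIL import Image

from .afm_image import HeightImage
from .concise_codec import BitMatrix
from .detailed_codec import SequenceLayout

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_matrix_image",
    "read_matrix_image",
    "read_height_tsv",
    "write_height_tsv",
    "write_height_pgm",
    "read_height_pgm",
    "write_layout_config",
    "read_layout_config",
]

# 16-bit height rasters store nm * HEIGHT_SCALE
HEIGHT_SCALE = 100.0


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs; raises ValueError on malformed records."""
    with _open_text(path, "r") as fh:
        try:
            return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    with _open_text(path, "w") as fh:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
            fh,
            "fasta",
        )


def read_fastq(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTQ; errors carry the record index."""
    out: list[tuple[str, str]] = []
    with _open_text(path, "r") as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                out.append((rec.id, str(rec.seq)))
        except ValueError as exc:
            raise ValueError(
                f"{path}: malformed FASTQ near record {len(out) + 1}: {exc}"
            ) from exc
    return out


def write_fastq(path, records: Iterable[tuple[str, str]], quality: str = "I") -> None:
    """Write FASTQ with a uniform synthetic quality character."""
    q = ord(quality) - 33
    with _open_text(path, "w") as fh:
        for rid, seq in records:
            rec = SeqRecord(Seq(seq), id=rid, description="")
            rec.letter_annotations["phred_quality"] = [q] * len(seq)
            SeqIO.write(rec, fh, "fastq")


# --------------------------------------------------------------------------
# matrices and height images


def write_matrix_tsv(path, m: BitMatrix) -> None:
    header = f"# pitch_nm={m.pitch_nm if m.pitch_nm is not None else 'none'}\n"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, m.bits, fmt="%d", delimiter="\t")


def read_matrix_tsv(path) -> BitMatrix:
    pitch = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            value = first.split("=", 1)[1].strip()
            pitch = None if value == "none" else float(value)
            bits = np.loadtxt(fh, dtype=np.uint8, delimiter="\t", ndmin=2)
        else:
            fh.seek(0)
            bits = np.loadtxt(fh, dtype=np.uint8, delimiter="\t", ndmin=2)
    return BitMatrix(bits, pitch_nm=pitch)


def write_matrix_image(path, m: BitMatrix) -> None:
    """8-bit grayscale raster: bit 1 -> 255, bit 0 -> 0 (PGM or PNG)."""
    Image.fromarray((m.bits * 255).astype(np.uint8), mode="L").save(path)


def read_matrix_image(path) -> BitMatrix:
    arr = np.asarray(Image.open(path).convert("L"))
    return BitMatrix((arr > 127).astype(np.uint8))


def write_height_tsv(path, img: HeightImage) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pixel_size_nm={img.pixel_size_nm}\n")
        np.savetxt(fh, img.heights, fmt="%.6g", delimiter="\t")


def read_height_tsv(path) -> HeightImage:
    with open(path) as fh:
        first = fh.readline()
        px = float(first.split("=", 1)[1]) if first.startswith("#") else 5.0
        if not first.startswith("#"):
            fh.seek(0)
        heights = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return HeightImage(heights, pixel_size_nm=px)


def write_height_pgm(path, img: HeightImage) -> None:
    """16-bit PGM; values are nm * 100, offset so the minimum maps to 0."""
    h = img.heights - img.heights.min()
    scaled = np.clip(h * HEIGHT_SCALE, 0, 65535).astype(">u2")
    with open(path, "wb") as fh:
        fh.write(f"P5\n# pixel_size_nm={img.pixel_size_nm}\n"
                 f"{scaled.shape[1]} {scaled.shape[0]}\n65535\n".encode())
        fh.write(scaled.tobytes())


def read_height_pgm(path) -> HeightImage:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"P5":
            raise ValueError(f"{path}: not a binary PGM file")
        px = 5.0
        line = fh.readline()
        while line.startswith(b"#"):
            if b"pixel_size_nm=" in line:
                px = float(line.split(b"=", 1)[1])
            line = fh.readline()
        w, h = map(int, line.split())
        maxval = int(fh.readline())
        if maxval != 65535:
            raise ValueError(f"{path}: expected a 16-bit PGM")
        data = np.frombuffer(fh.read(w * h * 2), dtype=">u2").reshape(h, w)
    return HeightImage(data.astype(float) / HEIGHT_SCALE, pixel_size_nm=px)


# --------------------------------------------------------------------------
# layout config


def write_layout_config(path, layout: SequenceLayout) -> None:
    with open(path, "w") as fh:
        for key, value in layout.to_config().items():
            fh.write(f"{key} = {value}\n")


def read_layout_config(path) -> SequenceLayout:
    fields = SequenceLayout.__dataclass_fields__
    kwargs = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown layout key {key!r}")
            typ = fields[key].type
            kwargs[key] = float(value) if "float" in str(typ) else int(value)
    return SequenceLayout(**kwargs)
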