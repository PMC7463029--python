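"""File IO: PLINK binary genotypes, GCTA binary GRMs, delimited tables,
and the text cine container.

PLINK .bed files start with magic bytes ``0x6C 0x1B`` and a mode byte
``0x01`` (SNP-major).  Each SNP record packs four samples per byte, first
sample in the lowest two bits, coded

=====  =======================
bits   meaning
=====  =======================
00     homozygous A1 (dosage 2)
01     missing
10     heterozygous (dosage 1)
11     homozygous A2 (dosage 0)
=====  =======================

GCTA's binary GRM stores the lower triangle row-major as little-endian
float32 (``.grm.bin``), the per-pair SNP counts the same way
(``.grm.N.bin``) and a two-column id list (``.grm.id``).

All writers are atomic: content goes to a temporary file that is renamed
into place, so a failed run leaves no partial output.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MISSING, GenotypeMatrix, Pedigree, SnpPanel
from .flow import CineFlowSeries
from .grm import GRM

__all__ = [
    "BED_MAGIC",
    "BfileSet",
    "write_bfile",
    "read_bfile",
    "write_grm",
    "read_grm",
    "write_metrics",
    "read_metrics",
    "write_cine",
    "read_cine",
    "atomic_write_text",
]

BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = bytes([0x01])

# dosage -> 2-bit code and back
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


@dataclass(frozen=True)
class BfileSet:
    """Paths of a .bed/.bim/.fam triplet."""

    prefix: Path

    @property
    def bed(self) -> Path:
        return Path(f"{self.prefix}.bed")

    @property
    def bim(self) -> Path:
        return Path(f"{self.prefix}.bim")

    @property
    def fam(self) -> Path:
        return Path(f"{self.prefix}.fam")

    def exists(self) -> bool:
        return self.bed.exists() and self.bim.exists() and self.fam.exists()


def atomic_write_text(path: Path, content: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(content)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_bytes(path: Path, content: bytes) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(content)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# PLINK binary
# ---------------------------------------------------------------------------

def write_bfile(
    genotypes: GenotypeMatrix,
    prefix,
    pedigree: Pedigree | None = None,
) -> BfileSet:
    """Write dosages + panel + sample registry as a PLINK binary triplet.

    The .fam carries pedigree links and sex when a pedigree is supplied;
    otherwise parents are 0 and sex unknown.
    """
    if genotypes.n == 0 or genotypes.m == 0:
        raise ValueError("refusing to write an empty cohort")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = genotypes.n, genotypes.m
    dos = genotypes.dosages
    codes = np.empty((m, n), dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[(dos == dosage).T] = code
    n_pad = (-n) % 4
    if n_pad:
        codes = np.hstack([codes, np.zeros((m, n_pad), dtype=np.uint8)])
    quads = codes.reshape(m, -1, 4)
    packed = (quads[:, :, 0] | (quads[:, :, 1] << 2)
              | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)).astype(np.uint8)
    _atomic_write_bytes(Path(f"{prefix}.bed"),
                        BED_MAGIC + _SNP_MAJOR + packed.tobytes())

    pt = genotypes.panel.table
    bim = pd.DataFrame({
        "chrom": pt["chrom"], "snp": pt["snp"], "cm": 0,
        "pos": pt["pos"], "a1": pt["a1"], "a2": pt["a2"],
    })
    atomic_write_text(Path(f"{prefix}.bim"),
                      bim.to_csv(sep="\t", index=False, header=False))

    if pedigree is not None:
        pos = {r.id: r for r in pedigree.table.itertuples(index=False)}
        rows = []
        for iid in genotypes.ids:
            r = pos.get(iid)
            if r is None:
                rows.append(("0", iid, "0", "0", 0, -9))
            else:
                rows.append((r.family, iid, r.father or "0", r.mother or "0",
                             1 if r.sex == "male" else 2, -9))
    else:
        rows = [("0", iid, "0", "0", 0, -9) for iid in genotypes.ids]
    fam = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex", "pheno"])
    atomic_write_text(Path(f"{prefix}.fam"),
                      fam.to_csv(sep="\t", index=False, header=False))
    return BfileSet(prefix)


def read_bfile(prefix) -> tuple[GenotypeMatrix, SnpPanel, pd.DataFrame]:
    """Read a PLINK binary triplet; dosage counts copies of the A1 allele.

    Raises on a bad magic number, a non-SNP-major mode byte, or a .bed
    payload whose length disagrees with the .bim/.fam dimensions.
    """
    files = BfileSet(Path(prefix))
    if not files.exists():
        raise FileNotFoundError(f"incomplete bfile triplet at {prefix}")
    bim = pd.read_csv(files.bim, sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"snp": str, "a1": str, "a2": str})
    fam = pd.read_csv(files.fam, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"fid": str, "iid": str, "father": str, "mother": str})
    n, m = len(fam), len(bim)
    raw = files.bed.read_bytes()
    if raw[:2] != BED_MAGIC:
        raise ValueError(".bed magic bytes invalid (not a PLINK binary file)")
    if raw[2:3] != _SNP_MAJOR:
        raise ValueError("only SNP-major .bed files are supported")
    rec = (n + 3) // 4
    if len(raw) != 3 + rec * m:
        raise ValueError(
            f".bed payload truncated or inconsistent: expected {3 + rec * m} "
            f"bytes for {n} samples x {m} SNPs, found {len(raw)}"
        )
    data = np.frombuffer(raw[3:], dtype=np.uint8).reshape(m, rec)
    codes = np.empty((m, rec * 4), dtype=np.uint8)
    codes[:, 0::4] = data & 0b11
    codes[:, 1::4] = (data >> 2) & 0b11
    codes[:, 2::4] = (data >> 4) & 0b11
    codes[:, 3::4] = (data >> 6) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()
    panel = SnpPanel(pd.DataFrame({
        "snp": bim["snp"], "chrom": bim["chrom"], "pos": bim["pos"],
        "a1": bim["a1"], "a2": bim["a2"], "freq": np.nan,
    }))
    genotypes = GenotypeMatrix(dosages, list(fam["iid"]), panel)
    return genotypes, panel, fam


def read_pedmap(prefix) -> tuple[GenotypeMatrix, SnpPanel, pd.DataFrame]:
    """Read PLINK *text* format (.ped/.map), as a read-only convenience.

    Binary bed/bim/fam is the canonical carrier; this reader exists for
    hand-written fixtures and interoperability.  Alleles are taken from
    the data, with the first allele seen per SNP counted as A1.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(f"{prefix}.map", sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos"], dtype={"snp": str})
    rows = []
    fam_rows = []
    for line in Path(f"{prefix}.ped").read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        fam_rows.append(parts[:6])
        rows.append(parts[6:])
    m = len(bim)
    n = len(rows)
    a1 = [None] * m
    dosages = np.full((n, m), MISSING, dtype=np.int8)
    for j, alleles in enumerate(rows):
        if len(alleles) != 2 * m:
            raise ValueError(f".ped line {j + 1} has {len(alleles)} alleles, "
                             f"expected {2 * m}")
        for i in range(m):
            pair = alleles[2 * i:2 * i + 2]
            if "0" in pair:
                continue
            if a1[i] is None:
                a1[i] = pair[0]
            dosages[j, i] = sum(al == a1[i] for al in pair)
    fam = pd.DataFrame(fam_rows, columns=["fid", "iid", "father", "mother",
                                          "sex", "pheno"])
    panel = SnpPanel(pd.DataFrame({
        "snp": bim["snp"], "chrom": bim["chrom"], "pos": bim["pos"],
        "a1": [a or "0" for a in a1], "a2": "?", "freq": np.nan,
    }))
    return GenotypeMatrix(dosages, list(fam["iid"]), panel), panel, fam


# ---------------------------------------------------------------------------
# GCTA binary GRM
# ---------------------------------------------------------------------------

def write_grm(grm: GRM, prefix, fam_ids: list[str] | None = None) -> None:
    """Write a GRM in GCTA's binary convention (plus readable ids)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = grm.n
    tri = np.tril_indices(n)
    _atomic_write_bytes(Path(f"{prefix}.grm.bin"),
                        grm.a[tri].astype("<f4").tobytes())
    _atomic_write_bytes(Path(f"{prefix}.grm.N.bin"),
                        grm.n_pairs[tri].astype("<f4").tobytes())
    fids = fam_ids if fam_ids is not None else ["0"] * n
    lines = "".join(f"{f}\t{i}\n" for f, i in zip(fids, grm.ids))
    atomic_write_text(Path(f"{prefix}.grm.id"), lines)


def write_grm_text(grm: GRM, path) -> None:
    """Plain-text GRM alternative: one lower-triangle entry per line
    (i, j, SNP count, relationship), 1-based indices."""
    lines = ["i\tj\tn_snps\ta\n"]
    for i in range(grm.n):
        for j in range(i + 1):
            lines.append(f"{i + 1}\t{j + 1}\t{int(grm.n_pairs[i, j])}\t"
                         f"{grm.a[i, j]:.10g}\n")
    atomic_write_text(Path(path), "".join(lines))


def read_grm(prefix) -> GRM:
    prefix = Path(prefix)
    ids_df = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None,
                         names=["fid", "iid"], dtype=str)
    n = len(ids_df)
    vals = np.frombuffer(Path(f"{prefix}.grm.bin").read_bytes(), dtype="<f4")
    counts = np.frombuffer(Path(f"{prefix}.grm.N.bin").read_bytes(), dtype="<f4")
    if vals.size != n * (n + 1) // 2:
        raise ValueError("GRM binary size inconsistent with id list")
    a = np.zeros((n, n))
    npair = np.zeros((n, n))
    tri = np.tril_indices(n)
    a[tri] = vals
    npair[tri] = counts
    a = a + np.tril(a, -1).T
    npair = npair + np.tril(npair, -1).T
    m = int(npair.max()) if n else 0
    return GRM(a, npair.astype(np.int64), list(ids_df["iid"]), m)


# ---------------------------------------------------------------------------
# metric tables
# ---------------------------------------------------------------------------

_METRIC_UNITS = {
    "id": "-", "csa_mm2": "mm^2", "diameter_m": "m",
    "u_pm": "m/s", "u_max": "m/s", "re_pm": "-", "re_max": "-",
}


def write_metrics(metrics: pd.DataFrame, path) -> None:
    """Tab-delimited per-subject metrics with a units header row."""
    cols = list(metrics.columns)
    units = "\t".join(_METRIC_UNITS.get(c, "-") for c in cols)
    body = metrics.to_csv(sep="\t", index=False)
    header, _, rest = body.partition("\n")
    atomic_write_text(Path(path), f"{header}\n{units}\n{rest}")


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", skiprows=[1])
    return df


# ---------------------------------------------------------------------------
# cine container (text frames + JSON sidecar, or a single HDF5 file)
# ---------------------------------------------------------------------------

def write_cine(series: CineFlowSeries, directory) -> Path:
    """One delimited matrix per frame, a mask matrix, and a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in range(series.n_frames):
        frame_txt = "\n".join(
            "\t".join(f"{v:.6g}" for v in row) for row in series.frames[t]
        )
        atomic_write_text(directory / f"frame_{t:03d}.tsv", frame_txt + "\n")
    mask_txt = "\n".join(
        "\t".join(str(int(v)) for v in row) for row in series.mask
    )
    atomic_write_text(directory / "mask.tsv", mask_txt + "\n")
    sidecar = {
        "n_frames": series.n_frames,
        "grid_shape": list(series.mask.shape),
        "pixel_spacing_mm": list(series.pixel_spacing_mm),
        "frame_interval_ms": series.frame_interval_ms,
        "units": series.units,
        "venc": series.venc,
        "mask_file": "mask.tsv",
    }
    atomic_write_text(directory / "cine.json", json.dumps(sidecar, indent=2))
    return directory


def read_cine(directory) -> CineFlowSeries:
    directory = Path(directory)
    sidecar = json.loads((directory / "cine.json").read_text())
    mask = np.loadtxt(directory / sidecar["mask_file"], dtype=int).astype(bool)
    frames = np.stack([
        np.loadtxt(directory / f"frame_{t:03d}.tsv")
        for t in range(sidecar["n_frames"])
    ])
    return CineFlowSeries(
        frames=frames,
        mask=mask,
        pixel_spacing_mm=tuple(sidecar["pixel_spacing_mm"]),
        frame_interval_ms=sidecar["frame_interval_ms"],
        units=sidecar.get("units", "m/s"),
        venc=sidecar.get("venc"),
    )


def write_cine_h5(series: CineFlowSeries, path) -> Path:
    """Single-container alternative using HDF5 (same named members)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("frames", data=series.frames)
        fh.create_dataset("mask", data=series.mask)
        fh.attrs["pixel_spacing_mm"] = series.pixel_spacing_mm
        fh.attrs["frame_interval_ms"] = series.frame_interval_ms
        fh.attrs["units"] = series.units
    return path


def read_cine_h5(path) -> CineFlowSeries:
    import h5py

    with h5py.File(path, "r") as fh:
        return CineFlowSeries(
            frames=fh["frames"][()],
            mask=fh["mask"][()].astype(bool),
            pixel_spacing_mm=tuple(fh.attrs["pixel_spacing_mm"]),
            frame_interval_ms=float(fh.attrs["frame_interval_ms"]),
            units=str(fh.attrs["units"]),
        )
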