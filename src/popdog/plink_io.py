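"""PLINK 1 genotype file I/O.

Readers and writers for the two PLINK dialects used for SNP-array data:

* text PED/MAP, and
* binary BED/BIM/FAM (SNP-major, magic bytes ``6C 1B 01``), with the 2-bit
  genotype packing of the PLINK 1 specification.

On read, ``allele_b`` (the allele whose copies the genotype codes count) is
chosen as the minor allele per SNP, ties at frequency 0.5 broken by
lexicographic order. The PED/FAM family-ID column is used as the population
label; a two-column sidecar TSV (``individual_id<TAB>population``) overrides
it.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .panel import MISSING, GenotypePanel, Individual, SnpRecord

_MAGIC = b"\x6c\x1b\x01"

# PLINK 2-bit code -> copies of allele A1; our A1 is allele_b
_BITS_TO_GENO = np.array([2, MISSING, 1, 0], dtype=np.int8)
_GENO_TO_BITS = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

_SEX = {"1": "male", "2": "female"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}


class PlinkParseError(ValueError):
    """Malformed PLINK input."""


def _read_population_map(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise PlinkParseError(
                f"{path}:{lineno}: expected 2 tab-separated columns"
            )
        mapping[parts[0]] = parts[1]
    return mapping


def _read_map(map_path: str | Path) -> list[tuple[str, str, int]]:
    """Return (chrom, id, pos) per marker from a MAP or first-4-column BIM."""
    out = []
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise PlinkParseError(
                f"{map_path}:{lineno}: expected >=4 whitespace-separated columns"
            )
        chrom, snp_id, _cm, pos = parts[:4]
        try:
            pos_bp = int(pos)
        except ValueError as exc:
            raise PlinkParseError(
                f"{map_path}:{lineno}: bad position {pos!r}"
            ) from exc
        out.append((chrom, snp_id, pos_bp))
    return out


def _choose_minor(counts: dict[str, int]) -> tuple[str, str]:
    """Return (allele_a=major, allele_b=minor); lexicographic tie-break."""
    alleles = sorted(counts)  # lexicographic baseline
    if len(alleles) == 1:
        return alleles[0], "0"  # monomorphic: placeholder minor allele
    a, b = alleles
    if counts[a] == counts[b]:
        return b, a  # tie: lexicographically first allele is the minor one
    return (a, b) if counts[a] > counts[b] else (b, a)


def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    population_map: str | Path | None = None,
) -> GenotypePanel:
    """Read a PED/MAP pair into a :class:`GenotypePanel`.

    Allele calls of ``0`` decode to MISSING; a SNP with more than two
    observed alleles raises :class:`PlinkParseError`.
    """
    markers = _read_map(map_path)
    n_snps = len(markers)
    individuals: list[Individual] = []
    raw_calls: list[list[tuple[str, str]]] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_snps:
            raise PlinkParseError(
                f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields, "
                f"got {len(parts)}"
            )
        fid, iid, _pat, _mat, sex, _pheno = parts[:6]
        individuals.append(
            Individual(id=iid, population=fid, sex=_SEX.get(sex, "unknown"))
        )
        raw_calls.append(
            [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_snps)]
        )
    if not individuals:
        raise PlinkParseError(f"{ped_path}: no individuals")

    snps: list[SnpRecord] = []
    geno = np.full((len(individuals), n_snps), MISSING, dtype=np.int8)
    for j, (chrom, snp_id, pos_bp) in enumerate(markers):
        counts: dict[str, int] = {}
        for row in raw_calls:
            for allele in row[j]:
                if allele != "0":
                    counts[allele] = counts.get(allele, 0) + 1
        if len(counts) > 2:
            raise PlinkParseError(
                f"SNP {snp_id}: {len(counts)} alleles observed; "
                "biallelic data required"
            )
        if counts:
            allele_a, allele_b = _choose_minor(counts)
        else:
            allele_a, allele_b = "A", "0"  # fully missing SNP
        for i, row in enumerate(raw_calls):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue  # half-calls and no-calls are MISSING
            geno[i, j] = (a1 == allele_b) + (a2 == allele_b)
        snps.append(SnpRecord(snp_id, chrom, pos_bp, allele_a, allele_b))

    panel = GenotypePanel(individuals, snps, geno)
    if population_map is not None:
        panel = _apply_population_map(panel, population_map)
    return panel


def _apply_population_map(
    panel: GenotypePanel, population_map: str | Path
) -> GenotypePanel:
    mapping = _read_population_map(population_map)
    individuals = [
        Individual(ind.id, mapping.get(ind.id, ind.population), ind.sex)
        for ind in panel.individuals
    ]
    return GenotypePanel(individuals, panel.snps, panel.genotypes)


def write_plink_text(
    panel: GenotypePanel, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write PED/MAP. Monomorphic placeholder alleles round-trip as missing."""
    with open(map_path, "w") as fh:
        for s in panel.snps:
            fh.write(f"{s.chrom}\t{s.id}\t0\t{s.pos_bp}\n")
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(panel.individuals):
            fields = [ind.population, ind.id, "0", "0", _SEX_OUT[ind.sex], "-9"]
            for j, s in enumerate(panel.snps):
                g = panel.genotypes[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [s.allele_a, s.allele_a]
                elif g == 1:
                    fields += [s.allele_a, s.allele_b]
                else:
                    fields += [s.allele_b, s.allele_b]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# binary BED/BIM/FAM
# ---------------------------------------------------------------------------

def read_plink_bed(
    bed_path: str | Path,
    bim_path: str | Path,
    fam_path: str | Path,
    population_map: str | Path | None = None,
) -> GenotypePanel:
    """Read a PLINK 1 binary fileset (SNP-major) into a panel.

    BIM allele 1 is taken as ``allele_b`` (PLINK's minor-allele slot), so the
    2-bit code's A1 dosage is the stored genotype code directly.
    """
    individuals: list[Individual] = []
    for lineno, line in enumerate(Path(fam_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 6:
            raise PlinkParseError(f"{fam_path}:{lineno}: expected 6 columns")
        fid, iid, _pat, _mat, sex, _pheno = parts[:6]
        individuals.append(
            Individual(id=iid, population=fid, sex=_SEX.get(sex, "unknown"))
        )

    snps: list[SnpRecord] = []
    for lineno, line in enumerate(Path(bim_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise PlinkParseError(f"{bim_path}:{lineno}: expected 6 columns")
        chrom, snp_id, _cm, pos, a1, a2 = parts
        snps.append(SnpRecord(snp_id, chrom, int(pos), allele_a=a2, allele_b=a1))

    raw = Path(bed_path).read_bytes()
    if raw[:2] != _MAGIC[:2]:
        raise PlinkParseError(f"{bed_path}: bad magic bytes")
    if len(raw) < 3 or raw[2] != 0x01:
        raise PlinkParseError(f"{bed_path}: not SNP-major (mode byte != 0x01)")
    n_ind, n_snps = len(individuals), len(snps)
    bytes_per_snp = math.ceil(n_ind / 4)
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != n_snps * bytes_per_snp:
        raise PlinkParseError(
            f"{bed_path}: body has {body.size} bytes, expected "
            f"{n_snps * bytes_per_snp} for {n_ind} individuals x {n_snps} SNPs"
        )
    body = body.reshape(n_snps, bytes_per_snp)
    # expand each byte into four 2-bit codes, low bits first (PLINK order)
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    geno = _BITS_TO_GENO[codes[:, :n_ind]].T.copy()

    panel = GenotypePanel(individuals, snps, geno)
    if population_map is not None:
        panel = _apply_population_map(panel, population_map)
    return panel


def write_plink_bed(
    panel: GenotypePanel,
    bed_path: str | Path,
    bim_path: str | Path,
    fam_path: str | Path,
) -> None:
    """Write a PLINK 1 binary fileset, bit-exact SNP-major packing."""
    with open(fam_path, "w") as fh:
        for ind in panel.individuals:
            fh.write(
                f"{ind.population} {ind.id} 0 0 {_SEX_OUT[ind.sex]} -9\n"
            )
    with open(bim_path, "w") as fh:
        for s in panel.snps:
            fh.write(
                f"{s.chrom}\t{s.id}\t0\t{s.pos_bp}\t{s.allele_b}\t{s.allele_a}\n"
            )
    n_ind = panel.n_individuals
    bytes_per_snp = math.ceil(n_ind / 4)
    bits = np.vectorize(_GENO_TO_BITS.__getitem__, otypes=[np.uint8])(
        panel.genotypes.T
    )  # (n_snps, n_ind)
    padded = np.full((panel.n_snps, bytes_per_snp * 4), 0, dtype=np.uint8)
    padded[:, :n_ind] = bits
    packed = np.zeros((panel.n_snps, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(bed_path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())
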