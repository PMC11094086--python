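"""Synthetic inputs with planted ground truth.

Everything the pipeline consumes can be generated here: a toy genome with
single-transcript multi-exon genes (valid ATG..stop CDS, GT..AG introns
carrying a branch-point box), the matching GTF and canonical proteome,
rMATS-dialect event tables whose junction counts are binomial draws around
planted true PSI values, and log2 intensity matrices with planted group
effects and missing-not-at-random dropout.

Planted neoepitopes come in two flavours mirroring the productive event
classes: retained introns rewritten so in-frame readthrough encodes a known
peptide before a stop codon, and skipped exons whose flanking coding
sequence is rewritten so the exclusion junction spells a known peptide.
Planted peptides are guaranteed absent from the canonical proteome
(re-randomised on collision).

Generators are bit-reproducible under a fixed seed. Toy genes use phase-0
exon boundaries (each exon's CDS chunk a multiple of 3), single isoforms,
and a binomial (not negative-binomial) junction-count model — the simplest
model whose expectation matches the planted PSI.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_name

from ._seq import revcomp
from .diff_intensity import IntensityMatrix
from .neopeptides import GeneModel, translate_cds
from .splice_events import RMATS_COLUMNS, compute_psi

_STANDARD = unambiguous_dna_by_name["Standard"]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_STANDARD.forward_table.items()):
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
STOP_CODONS = tuple(sorted(_STANDARD.stop_codons))
AMINO_ACIDS = "".join(sorted(_AA_TO_CODONS))
DNA = "ACGT"

# branch-point box matching the consensus PWM (branch A at index 3)
_BP_BOX_CORE = "TTTAC"


class CoordinateError(ValueError):
    pass


class PlacementError(ValueError):
    pass


@dataclass
class ToyGenome:
    chrom_sequences: dict[str, str]
    seed: int

    def __post_init__(self):
        for name, seq in self.chrom_sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            if set(seq) - set(DNA):
                raise ValueError(f"chromosome {name!r} has non-ACGT letters")


@dataclass
class PlantedEventTruth:
    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    coords: dict[str, int]
    true_psi_control: float
    true_psi_treated: float
    is_significant: bool
    planted_peptides: list[str] = field(default_factory=list)

    def __post_init__(self):
        delta = abs(self.true_psi_treated - self.true_psi_control)
        if self.is_significant != (delta > 0.1):
            raise ValueError(
                "is_significant must equal (|true dPSI| > 0.1) by construction"
            )
        for p in self.planted_peptides:
            if not 8 <= len(p) <= 14:
                raise ValueError(f"planted peptide {p!r} outside 8-14mer range")


@dataclass
class PlantedIntensityTruth:
    feature_id: str
    group_effect: float  # log2 fold change, treated - control
    is_null: bool
    dropout_rate: float = 0.0

    def __post_init__(self):
        if self.is_null != (self.group_effect == 0):
            raise ValueError("is_null must equal (group_effect == 0)")


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------


def _random_protein(n_aa: int, rng) -> str:
    return "M" + "".join(rng.choice(list(AMINO_ACIDS), size=n_aa - 1))


def _backtranslate(protein: str, rng) -> str:
    return "".join(
        _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))] for aa in protein
    )


def _random_dna(n: int, rng) -> str:
    return "".join(rng.choice(list(DNA), size=n))


def _make_intron(length: int, rng) -> str:
    """GT..AG intron with a planted branch-point box and pyrimidine tract."""
    if length < 60:
        raise ValueError("intron too short")
    seq = list(_random_dna(length, rng))
    seq[0:2] = "GT"
    seq[-2:] = "AG"
    dist = int(rng.integers(20, 41))  # branch A distance to the 3'ss
    i = length - 1 - dist  # index of the branch adenosine
    box = _BP_BOX_CORE + _random_dna(2, rng)
    seq[i - 3 : i + 4] = box
    for j in range(i + 4, length - 2):  # pyrimidine tract, no competing A
        seq[j] = "CT"[rng.integers(2)]
    return "".join(seq)


def make_toy_genome(
    n_genes: int,
    seed: int,
    chrom: str = "chr1",
    exons_per_gene: tuple[int, int] = (3, 5),
    codons_per_exon: tuple[int, int] = (25, 60),
    intron_length: tuple[int, int] = (80, 150),
    utr_length: int = 30,
    spacer: int = 150,
):
    """Toy genome, gene models and canonical proteome.

    Each gene is a single transcript on a random strand: 5'UTR, multi-exon
    CDS with phase-0 exon boundaries starting ATG and ending with a stop
    codon, 3'UTR. Returns ``(ToyGenome, {gene_id: GeneModel}, proteome)``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_parts = [_random_dna(spacer, rng)]
    offset = spacer
    models: dict[str, GeneModel] = {}
    for g in range(n_genes):
        gene_id = f"gene{g + 1}"
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        chunk_codons = [
            int(rng.integers(codons_per_exon[0], codons_per_exon[1] + 1))
            for _ in range(n_ex)
        ]
        n_codons = sum(chunk_codons)  # includes the stop codon
        protein = _random_protein(n_codons - 1, rng)
        cds_nt = _backtranslate(protein, rng) + STOP_CODONS[rng.integers(len(STOP_CODONS))]
        chunks, pos = [], 0
        for c in chunk_codons:
            chunks.append(cds_nt[pos : pos + 3 * c])
            pos += 3 * c
        utr5 = _random_dna(utr_length, rng)
        utr3 = _random_dna(utr_length, rng)
        introns = [
            _make_intron(int(rng.integers(intron_length[0], intron_length[1] + 1)), rng)
            for _ in range(n_ex - 1)
        ]
        strand = "+-"[rng.integers(2)]

        # local (transcript-orientation) layout
        exon_seqs = [utr5 + chunks[0]] + chunks[1:-1] + [chunks[-1] + utr3]
        if n_ex == 1:
            exon_seqs = [utr5 + chunks[0] + utr3]
        local_exons, local_cds, cursor = [], [], 0
        for i, es in enumerate(exon_seqs):
            start = cursor
            end = cursor + len(es)
            local_exons.append((start, end))
            a = start + (utr_length if i == 0 else 0)
            b = end - (utr_length if i == n_ex - 1 else 0)
            local_cds.append((a, b))
            cursor = end
            if i < n_ex - 1:
                cursor += len(introns[i])
        gene_local = "".join(
            es + (introns[i] if i < n_ex - 1 else "")
            for i, es in enumerate(exon_seqs)
        )
        L = len(gene_local)
        if strand == "+":
            placed = gene_local
            g_exons = [(offset + s, offset + e) for s, e in local_exons]
            g_cds = [(offset + a, offset + b) for a, b in local_cds]
        else:
            placed = revcomp(gene_local)
            g_exons = [(offset + L - e, offset + L - s) for s, e in local_exons]
            g_cds = [(offset + L - b, offset + L - a) for a, b in local_cds]
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            transcript_id=f"{gene_id}.t1",
            chrom=chrom,
            strand=strand,
            exons=g_exons,
            cds=g_cds,
        )
        chrom_parts.append(placed)
        chrom_parts.append(_random_dna(spacer, rng))
        offset += L + spacer
    genome = ToyGenome({chrom: "".join(chrom_parts)}, seed=seed)
    proteome = proteome_from_models(genome, models)
    return genome, models, proteome


def proteome_from_models(genome, models: dict[str, GeneModel]) -> dict[str, str]:
    return {gid: m.protein(genome) for gid, m in models.items()}


# ---------------------------------------------------------------------------
# FASTA / GTF writers
# ---------------------------------------------------------------------------


def write_fasta(records: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_genome_fasta(genome: ToyGenome, path) -> None:
    write_fasta(genome.chrom_sequences, path)


def write_gtf(models: dict[str, GeneModel], path) -> None:
    """GTF with gene/transcript/exon/CDS features, 1-based inclusive."""
    with open(path, "w") as fh:
        for gid in sorted(models):
            m = models[gid]
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            span = (m.exons[0][0], m.exons[-1][1])
            for ftype, ivs in (
                ("gene", [span]),
                ("transcript", [span]),
                ("exon", m.exons),
                ("CDS", m.cds),
            ):
                for s, e in ivs:
                    fh.write(
                        f"{m.chrom}\ttoy\t{ftype}\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Neoepitope planting
# ---------------------------------------------------------------------------


def _rewrite_tx_segment(genome: ToyGenome, chrom: str, strand: str,
                        interval: tuple[int, int], new_tx_seq: str) -> None:
    s, e = interval
    if len(new_tx_seq) != e - s:
        raise ValueError("replacement length mismatch")
    repl = new_tx_seq if strand == "+" else revcomp(new_tx_seq)
    seq = genome.chrom_sequences[chrom]
    genome.chrom_sequences[chrom] = seq[:s] + repl + seq[e:]


def _exon_cds_local(m: GeneModel):
    """Per transcript-order exon: (genomic interval, CDS tx-local [a, b))."""
    out = []
    for s, e in m.exons_tx():
        overlaps = [
            (max(s, c0), min(e, c1)) for c0, c1 in m.cds if c1 > s and c0 < e
        ]
        if not overlaps:
            out.append(((s, e), None))
            continue
        cs, ce = overlaps[0]
        if m.strand == "+":
            out.append(((s, e), (cs - s, ce - s)))
        else:
            out.append(((s, e), (e - ce, e - cs)))
    return out


def _tx_local_to_genomic(exon: tuple[int, int], strand: str, a: int, b: int):
    s, e = exon
    return (s + a, s + b) if strand == "+" else (e - b, e - a)


def _collides(peptide: str, proteome: dict[str, str]) -> bool:
    return any(peptide in p for p in proteome.values())


def plant_neoepitope(
    genome: ToyGenome,
    models: dict[str, GeneModel],
    gene_id: str,
    event_type: str,
    peptide: str | None = None,
    seed: int = 0,
    peptide_length: int = 10,
    max_tries: int = 50,
    true_psi: tuple[float, float] | None = None,
    event_number: int = 0,
) -> PlantedEventTruth:
    """Rewrite one gene in place so a productive splice variant encodes a
    known novel peptide.

    RI: an intron is rewritten so in-frame readthrough translates a Val
    followed by the peptide and a stop codon (true PSI defaults to
    0.1 -> 0.6, increased retention). SE: the coding sequence flanking an
    internal exon is rewritten so the exclusion junction spells the peptide
    (true PSI defaults 0.85 -> 0.35, decreased inclusion). A peptide
    colliding with the canonical proteome is re-randomised; an explicit
    peptide is the first attempt.
    """
    if event_type not in ("SE", "RI"):
        raise PlacementError(f"plantable event types are SE and RI, not {event_type!r}")
    m = models[gene_id]
    rng = np.random.default_rng(seed)
    k = len(peptide) if peptide else peptide_length
    if not 8 <= k <= 14:
        raise PlacementError("peptide length must be 8-14")
    exon_info = _exon_cds_local(m)
    n_ex = len(exon_info)

    if event_type == "RI":
        introns = m.introns()  # genomic, ascending
        tx_introns = introns if m.strand == "+" else introns[::-1]
        need = 3 + 3 * k + 3 + 2  # GTT + peptide + stop + trailing AG
        eligible = [i for i, (a, b) in enumerate(tx_introns) if b - a >= need + 4]
        if not eligible:
            raise PlacementError(f"{gene_id}: no intron long enough for a {k}-mer")
        idx = int(eligible[rng.integers(len(eligible))])
        g_intron = tx_introns[idx]
        L = g_intron[1] - g_intron[0]
        proteome = proteome_from_models(genome, models)
        for attempt in range(max_tries):
            pep = peptide if (peptide and attempt == 0) else "".join(
                rng.choice(list(AMINO_ACIDS), size=k)
            )
            if _collides(pep, proteome):
                continue
            body = "GTT" + _backtranslate(pep, rng) + STOP_CODONS[rng.integers(3)]
            filler = _random_dna(L - len(body) - 2, rng)
            _rewrite_tx_segment(genome, m.chrom, m.strand, g_intron, body + filler + "AG")
            break
        else:
            raise PlacementError(f"{gene_id}: could not place a collision-free peptide")
        # transcript-upstream/downstream exons flanking this intron
        exons_tx = m.exons_tx()
        up, down = exons_tx[idx], exons_tx[idx + 1]
        span = (min(up[0], down[0]), max(up[1], down[1]))
        psi_c, psi_t = true_psi or (0.10, 0.60)
        coords = {
            "riExonStart_0base": span[0], "riExonEnd": span[1],
            "upstreamES": up[0], "upstreamEE": up[1],
            "downstreamES": down[0], "downstreamEE": down[1],
        }
    else:  # SE
        internal = [
            j for j in range(1, n_ex - 1)
            if exon_info[j][1] is not None
            and (exon_info[j][1][1] - exon_info[j][1][0]) % 3 == 0
        ]
        if not internal:
            raise PlacementError(f"{gene_id}: no internal in-frame exon to skip")
        j = int(internal[rng.integers(len(internal))])
        h = k // 2
        (up_exon, up_cds) = exon_info[j - 1]
        (dn_exon, dn_cds) = exon_info[j + 1]
        if up_cds is None or dn_cds is None:
            raise PlacementError(f"{gene_id}: flanking exon lacks CDS")
        ua, ub = up_cds
        da, db = dn_cds
        if ub - 3 * h < ua + (3 if j - 1 == 0 else 0):
            raise PlacementError(f"{gene_id}: upstream exon too short for planting")
        if da + 3 * (k - h) > db - (3 if j + 1 == n_ex - 1 else 0):
            raise PlacementError(f"{gene_id}: downstream exon too short for planting")
        proteome = proteome_from_models(genome, models)
        skipped_chunk_aa = ""  # residues encoded by the skipped exon
        for attempt in range(max_tries):
            pep = peptide if (peptide and attempt == 0) else "".join(
                rng.choice(list(AMINO_ACIDS), size=k)
            )
            _rewrite_tx_segment(
                genome, m.chrom, m.strand,
                _tx_local_to_genomic(up_exon, m.strand, ub - 3 * h, ub),
                _backtranslate(pep[:h], rng),
            )
            _rewrite_tx_segment(
                genome, m.chrom, m.strand,
                _tx_local_to_genomic(dn_exon, m.strand, da, da + 3 * (k - h)),
                _backtranslate(pep[h:], rng),
            )
            proteome = proteome_from_models(genome, models)
            if not _collides(pep, proteome):
                break
        else:
            raise PlacementError(f"{gene_id}: could not place a collision-free peptide")
        skipped = m.exons_tx()[j]
        exons_tx = m.exons_tx()
        up, down = exons_tx[j - 1], exons_tx[j + 1]
        psi_c, psi_t = true_psi or (0.85, 0.35)
        coords = {
            "exonStart_0base": skipped[0], "exonEnd": skipped[1],
            "upstreamES": up[0], "upstreamEE": up[1],
            "downstreamES": down[0], "downstreamEE": down[1],
        }

    return PlantedEventTruth(
        event_id=f"{event_type}:{event_number}",
        event_type=event_type,
        gene_id=gene_id,
        chrom=m.chrom,
        strand=m.strand,
        coords=coords,
        true_psi_control=psi_c,
        true_psi_treated=psi_t,
        is_significant=abs(psi_t - psi_c) > 0.1,
        planted_peptides=[pep],
    )


# ---------------------------------------------------------------------------
# Filler event truths
# ---------------------------------------------------------------------------


def sample_event_truths(
    models: dict[str, GeneModel],
    n_events: int,
    frac_significant: float,
    seed: int,
    event_types=("SE", "RI", "MXE", "A3SS", "A5SS"),
    start_numbers: dict[str, int] | None = None,
) -> list[PlantedEventTruth]:
    """Random (non-neoepitope) event truths anchored on real gene structures.

    Significant truths get |true dPSI| in (0.25, 0.5]; non-significant in
    [0, 0.08]. Coordinates reuse annotated exons/introns so every event lies
    inside an emitted gene.
    """
    rng = np.random.default_rng(seed)
    counters = dict(start_numbers or {})
    gene_ids = sorted(models)
    out = []
    for _ in range(n_events):
        etype = event_types[rng.integers(len(event_types))]
        m = models[gene_ids[rng.integers(len(gene_ids))]]
        exons_tx = m.exons_tx()
        n_ex = len(exons_tx)
        if etype in ("SE", "MXE") and n_ex < 3:
            etype = "RI"
        if etype == "MXE" and n_ex < 4:
            etype = "SE"
        if etype == "SE":
            j = int(rng.integers(1, n_ex - 1))
            exon, up, down = exons_tx[j], exons_tx[j - 1], exons_tx[j + 1]
            coords = {
                "exonStart_0base": exon[0], "exonEnd": exon[1],
                "upstreamES": up[0], "upstreamEE": up[1],
                "downstreamES": down[0], "downstreamEE": down[1],
            }
        elif etype == "RI":
            introns = m.introns() if m.strand == "+" else m.introns()[::-1]
            j = int(rng.integers(len(introns)))
            exons = exons_tx
            up, down = exons[j], exons[j + 1]
            span = (min(up[0], down[0]), max(up[1], down[1]))
            coords = {
                "riExonStart_0base": span[0], "riExonEnd": span[1],
                "upstreamES": up[0], "upstreamEE": up[1],
                "downstreamES": down[0], "downstreamEE": down[1],
            }
        elif etype == "MXE":
            j = int(rng.integers(1, n_ex - 2))
            e1, e2 = exons_tx[j], exons_tx[j + 1]
            up, down = exons_tx[j - 1], exons_tx[min(j + 2, n_ex - 1)]
            first, second = sorted([e1, e2])
            coords = {
                "1stExonStart_0base": first[0], "1stExonEnd": first[1],
                "2ndExonStart_0base": second[0], "2ndExonEnd": second[1],
                "upstreamES": up[0], "upstreamEE": up[1],
                "downstreamES": down[0], "downstreamEE": down[1],
            }
        else:  # A3SS / A5SS: long exon extends into the intron between j-1 and j
            j = int(rng.integers(1, n_ex))
            ext = 9
            if etype == "A3SS":  # acceptor shift: downstream exon grows 5'-ward
                short, flank = exons_tx[j], exons_tx[j - 1]
                long_exon = (
                    (short[0] - ext, short[1]) if m.strand == "+" else (short[0], short[1] + ext)
                )
            else:  # A5SS, donor shift: upstream exon grows 3'-ward
                short, flank = exons_tx[j - 1], exons_tx[j]
                long_exon = (
                    (short[0], short[1] + ext) if m.strand == "+" else (short[0] - ext, short[1])
                )
            coords = {
                "longExonStart_0base": long_exon[0], "longExonEnd": long_exon[1],
                "shortES": short[0], "shortEE": short[1],
                "flankingES": flank[0], "flankingEE": flank[1],
            }
        significant = rng.random() < frac_significant
        if significant:
            delta = float(rng.uniform(0.25, 0.5)) * (1 if rng.random() < 0.5 else -1)
            lo, hi = (0.02, 0.98 - delta) if delta > 0 else (0.02 - delta, 0.98)
            psi_c = float(rng.uniform(lo, hi))
        else:
            delta = float(rng.uniform(0.0, 0.08)) * (1 if rng.random() < 0.5 else -1)
            psi_c = float(rng.uniform(max(0.02, -delta), min(0.98, 1 - delta)))
        n = counters.get(etype, 0)
        counters[etype] = n + 1
        out.append(
            PlantedEventTruth(
                event_id=f"{etype}:{n}",
                event_type=etype,
                gene_id=m.gene_id,
                chrom=m.chrom,
                strand=m.strand,
                coords=coords,
                true_psi_control=psi_c,
                true_psi_treated=psi_c + delta,
                is_significant=abs(delta) > 0.1,
                planted_peptides=[],
            )
        )
    return out


# ---------------------------------------------------------------------------
# rMATS table emission
# ---------------------------------------------------------------------------


def _effective_lengths(event_type: str, read_length: int) -> tuple[int, int]:
    j = read_length - 1
    if event_type in ("SE", "RI", "MXE"):
        return 2 * j, j
    return j, j  # A3SS / A5SS: one junction each


def _draw_counts(psi: float, n: int, lI: int, lS: int, rng) -> tuple[int, int]:
    p = psi * lI / (psi * lI + (1 - psi) * lS) if 0 < psi < 1 else float(psi >= 1)
    I = int(rng.binomial(n, p))
    return I, n - I


def plant_splice_events(
    genome: ToyGenome,
    truths: list[PlantedEventTruth],
    reads_per_event: int = 100,
    read_length: int = 50,
    seed: int = 0,
    n_replicates: int = 2,
    models: dict[str, GeneModel] | None = None,
    max_resample: int = 1000,
) -> dict[str, pd.DataFrame]:
    """rMATS 4.1.2 JC tables with binomial junction counts at the planted PSI.

    Sample 1 is the treated group. Significant truths get FDR 0.001 and
    counts resampled (bounded retries) until the realized |dPSI| clears the
    0.1 cut-off in the planted direction; others draw FDR uniform on
    (0.2, 1). Event coordinates are validated against the chromosome (and
    gene span when ``models`` is given).
    """
    if reads_per_event < 1:
        raise ValueError("reads_per_event must be >= 1")
    rng = np.random.default_rng(seed)
    rows_by_type: dict[str, list[dict]] = {t: [] for t in RMATS_COLUMNS}
    for truth in truths:
        chrom_len = len(genome.chrom_sequences[truth.chrom])
        for v in truth.coords.values():
            if not 0 <= v <= chrom_len:
                raise CoordinateError(
                    f"{truth.event_id}: coordinate {v} outside {truth.chrom}"
                )
        if models is not None and truth.gene_id in models:
            m = models[truth.gene_id]
            lo, hi = m.exons[0][0], m.exons[-1][1]
            for v in truth.coords.values():
                if not lo <= v <= hi:
                    raise CoordinateError(
                        f"{truth.event_id}: coordinate {v} outside gene "
                        f"{truth.gene_id} [{lo}, {hi}]"
                    )
        lI, lS = _effective_lengths(truth.event_type, read_length)
        planted_delta = truth.true_psi_treated - truth.true_psi_control
        for _ in range(max_resample):
            I1 = [_draw_counts(truth.true_psi_treated, reads_per_event, lI, lS, rng)
                  for _ in range(n_replicates)]
            I2 = [_draw_counts(truth.true_psi_control, reads_per_event, lI, lS, rng)
                  for _ in range(n_replicates)]
            _, psi1 = compute_psi([c[0] for c in I1], [c[1] for c in I1], lI, lS)
            _, psi2 = compute_psi([c[0] for c in I2], [c[1] for c in I2], lI, lS)
            delta = psi1 - psi2
            if not truth.is_significant:
                break
            if abs(delta) > 0.1 and math.copysign(1, delta) == math.copysign(1, planted_delta):
                break
        else:
            raise RuntimeError(f"{truth.event_id}: could not realize planted dPSI")
        if truth.is_significant:
            pval, fdr = 1e-5, 0.001
        else:
            pval = float(rng.uniform(0.1, 1.0))
            fdr = float(rng.uniform(0.2, 1.0))
        psi1_reps, _ = compute_psi([c[0] for c in I1], [c[1] for c in I1], lI, lS)
        psi2_reps, _ = compute_psi([c[0] for c in I2], [c[1] for c in I2], lI, lS)
        num_id = int(truth.event_id.split(":")[1])
        row = {
            "ID": num_id, "ID.1": num_id,
            "GeneID": truth.gene_id, "geneSymbol": truth.gene_id,
            "chr": truth.chrom, "strand": truth.strand,
            **truth.coords,
            "IJC_SAMPLE_1": [c[0] for c in I1], "SJC_SAMPLE_1": [c[1] for c in I1],
            "IJC_SAMPLE_2": [c[0] for c in I2], "SJC_SAMPLE_2": [c[1] for c in I2],
            "IncFormLen": lI, "SkipFormLen": lS,
            "PValue": pval, "FDR": fdr,
            "IncLevel1": ",".join("NA" if np.isnan(p) else repr(round(float(p), 6)) for p in psi1_reps),
            "IncLevel2": ",".join("NA" if np.isnan(p) else repr(round(float(p), 6)) for p in psi2_reps),
            "IncLevelDifference": round(delta, 6) if not np.isnan(delta) else "NA",
        }
        rows_by_type[truth.event_type].append(row)
    out = {}
    for etype, rows in rows_by_type.items():
        if not rows:
            continue
        out[etype] = pd.DataFrame(rows, columns=RMATS_COLUMNS[etype])
        out[etype]["event_type"] = etype
        out[etype]["event_id"] = etype + ":" + out[etype]["ID"].astype(str)
        out[etype]["gene_id"] = out[etype]["GeneID"]
    return out


# ---------------------------------------------------------------------------
# Intensity matrices
# ---------------------------------------------------------------------------


def make_intensity_truths(
    n_features: int, frac_nonnull: float, effect: float, seed: int
) -> list[PlantedIntensityTruth]:
    rng = np.random.default_rng(seed)
    n_alt = int(round(frac_nonnull * n_features))
    alt = set(rng.choice(n_features, size=n_alt, replace=False).tolist())
    return [
        PlantedIntensityTruth(
            feature_id=f"feat{i + 1}",
            group_effect=effect if i in alt else 0.0,
            is_null=i not in alt,
        )
        for i in range(n_features)
    ]


def simulate_intensity_matrix(
    n_features: int,
    n_per_group: int,
    truths: list[PlantedIntensityTruth],
    noise_sd: float,
    seed: int,
    baseline_mean: float = 25.0,
    baseline_sd: float = 2.0,
    dropout_mid: float | None = None,
    dropout_scale: float = 1.0,
) -> IntensityMatrix:
    """Log2 intensity matrix with planted group effects and MNAR dropout.

    value = baseline + effect * 1[treated] + N(0, noise_sd^2); entries are
    censored to missing with logistic probability
    1 / (1 + exp((x - dropout_mid) / dropout_scale)) — increasing as the
    intensity decreases. ``dropout_mid=None`` disables censoring. Realized
    per-feature dropout rates are written back onto the truths.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if len(truths) != n_features:
        raise ValueError("len(truths) must equal n_features")
    rng = np.random.default_rng(seed)
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_features)
    effects = np.array([t.group_effect for t in truths])
    n_samples = 2 * n_per_group
    noise = rng.normal(0.0, noise_sd, size=(n_features, n_samples)) if noise_sd > 0 \
        else np.zeros((n_features, n_samples))
    treated = np.array([0] * n_per_group + [1] * n_per_group)
    X = baseline[:, None] + effects[:, None] * treated[None, :] + noise
    if dropout_mid is not None:
        p_miss = 1.0 / (1.0 + np.exp((X - dropout_mid) / dropout_scale))
        X = np.where(rng.random(X.shape) < p_miss, np.nan, X)
    samples = [f"control_{i + 1}" for i in range(n_per_group)] + [
        f"treated_{i + 1}" for i in range(n_per_group)
    ]
    values = pd.DataFrame(X, index=[t.feature_id for t in truths], columns=samples)
    for i, t in enumerate(truths):
        t.dropout_rate = float(np.isnan(X[i]).mean())
    groups = pd.Series(["control"] * n_per_group + ["treated"] * n_per_group,
                       index=samples)
    return IntensityMatrix(values, groups)


# ---------------------------------------------------------------------------
# Mirroring (strand/coordinate property testing support)
# ---------------------------------------------------------------------------


def mirror_genome(genome: ToyGenome, models: dict[str, GeneModel]):
    """Reverse-complement every chromosome and remap annotations.

    Transcript-orientation quantities (features, maps, peptides) must be
    invariant under this transformation.
    """
    lengths = {c: len(s) for c, s in genome.chrom_sequences.items()}
    mirrored = ToyGenome(
        {c: revcomp(s) for c, s in genome.chrom_sequences.items()}, seed=genome.seed
    )
    def flip(iv, L):
        return (L - iv[1], L - iv[0])
    new_models = {}
    for gid, m in models.items():
        L = lengths[m.chrom]
        new_models[gid] = GeneModel(
            gene_id=m.gene_id,
            transcript_id=m.transcript_id,
            chrom=m.chrom,
            strand="-" if m.strand == "+" else "+",
            exons=[flip(e, L) for e in m.exons],
            cds=[flip(c, L) for c in m.cds],
        )
    return mirrored, new_models


_PAIRED_COLS = [
    ("exonStart_0base", "exonEnd"),
    ("riExonStart_0base", "riExonEnd"),
    ("1stExonStart_0base", "1stExonEnd"),
    ("2ndExonStart_0base", "2ndExonEnd"),
    ("longExonStart_0base", "longExonEnd"),
    ("upstreamES", "upstreamEE"),
    ("downstreamES", "downstreamEE"),
    ("shortES", "shortEE"),
    ("flankingES", "flankingEE"),
]


def mirror_events(df: pd.DataFrame, chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Remap event coordinates onto the mirrored genome (strands flipped,
    transcript-relative roles preserved)."""
    out = df.copy()
    L = out["chr"].map(chrom_lengths)
    for start_col, end_col in _PAIRED_COLS:
        if start_col in out.columns:
            s, e = out[start_col].copy(), out[end_col].copy()
            out[start_col] = L - e
            out[end_col] = L - s
    out["strand"] = out["strand"].map({"+": "-", "-": "+"})
    return out


# ---------------------------------------------------------------------------
# Whole-study convenience wrapper
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    genome: ToyGenome
    models: dict[str, GeneModel]
    proteome: dict[str, str]
    truths: list[PlantedEventTruth]
    tables: dict[str, pd.DataFrame]
    planted_peptides: list[str]


def make_synthetic_study(
    n_genes: int = 5,
    n_ri_neoepitopes: int = 3,
    n_se_neoepitopes: int = 2,
    n_filler_events: int = 20,
    reads_per_event: int = 100,
    read_length: int = 50,
    seed: int = 0,
) -> SyntheticStudy:
    """Toy genome with planted neoepitopes plus rMATS tables, ready to run
    end-to-end."""
    if n_ri_neoepitopes + n_se_neoepitopes > n_genes:
        raise ValueError("need at least one gene per planted neoepitope")
    genome, models, _ = make_toy_genome(n_genes, seed=seed)
    gene_ids = sorted(models)
    truths: list[PlantedEventTruth] = []
    counters = {"SE": 0, "RI": 0}
    # SE plantings rewrite canonical coding sequence, RI plantings do not;
    # planting SE first keeps every collision check valid against the final
    # proteome (re-verified below regardless).
    for i in range(n_se_neoepitopes):
        truths.append(
            plant_neoepitope(
                genome, models, gene_ids[i], "SE", seed=seed + 201 + i,
                event_number=counters["SE"],
            )
        )
        counters["SE"] += 1
    for i in range(n_ri_neoepitopes):
        truths.append(
            plant_neoepitope(
                genome, models, gene_ids[n_se_neoepitopes + i], "RI",
                seed=seed + 101 + i, event_number=counters["RI"],
            )
        )
        counters["RI"] += 1
    proteome = proteome_from_models(genome, models)
    planted = [p for t in truths for p in t.planted_peptides]
    for pep in planted:  # construction guarantee, re-checked on the final genome
        if _collides(pep, proteome):
            raise PlacementError(f"planted peptide {pep} collides after later edits")
    if n_filler_events:
        truths.extend(
            sample_event_truths(
                models, n_filler_events, frac_significant=0.3, seed=seed + 301,
                start_numbers=counters,
            )
        )
    tables = plant_splice_events(
        genome, truths, reads_per_event=reads_per_event,
        read_length=read_length, seed=seed + 401, models=models,
    )
    return SyntheticStudy(genome, models, proteome, truths, tables, planted)


def write_truth_table(truths: list[PlantedEventTruth], path) -> None:
    rows = [
        {
            "event_id": t.event_id, "event_type": t.event_type,
            "gene_id": t.gene_id, "chrom": t.chrom, "strand": t.strand,
            "true_psi_control": t.true_psi_control,
            "true_psi_treated": t.true_psi_treated,
            "is_significant": t.is_significant,
            "planted_peptides": ",".join(t.planted_peptides),
        }
        for t in truths
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
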