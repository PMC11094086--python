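"""Splicing-derived neoantigen candidate generation.

Reconstructs the altered transcript implied by a "productive" alternative
splicing event (skipped-exon *exclusion* or retained-intron *inclusion*),
translates it under conservative assumptions — annotated canonical START
only, translation to the first stop codon, no readthrough and no internal
initiation — digests the protein into unique 8–14mers, and keeps the
peptides absent from the canonical proteome as neoantigen candidates.
Binding prediction is interfaced: either NetMHCpan-style tabular output is
joined onto the candidates, or a transparent toy anchor-matrix scorer ranks
9-mers against a proteome-sampled background (for offline testing only; it
makes no biological claim).

Gene models are single-isoform: one transcript per gene, exons non-
overlapping, CDS a subset of the exons beginning with ATG. Coordinates are
0-based half-open internally; GTF input is 1-based inclusive. The CDS
intervals here INCLUDE the stop codon (translation runs to the first stop,
so the convention only affects bookkeeping).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._seq import fetch, revcomp

# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """Single-transcript gene structure.

    ``exons`` and ``cds`` are genomic (plus-strand) 0-based half-open
    intervals sorted by genomic start; transcript order is genomic order on
    '+' and reversed on '-'.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self):
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for (s, e), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    # -- transcript-order views ------------------------------------------
    def exons_tx(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def introns(self) -> list[tuple[int, int]]:
        """Genomic gaps between consecutive exons, ascending."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def canonical_start(self) -> int:
        """Genomic coordinate of the first base of the start codon."""
        return self.cds[0][0] if self.strand == "+" else self.cds[-1][1] - 1

    @property
    def cds_last_base(self) -> int:
        """Genomic coordinate of the final CDS base (end of stop codon)."""
        return self.cds[-1][1] - 1 if self.strand == "+" else self.cds[0][0]

    def transcript_seq(self, genome) -> str:
        return _chain_seq(genome, self.chrom, self.strand, self.exons_tx())

    def cds_seq(self, genome) -> str:
        chain = self.cds if self.strand == "+" else self.cds[::-1]
        return _chain_seq(genome, self.chrom, self.strand, chain)

    def protein(self, genome) -> str:
        return translate_cds(self.cds_seq(genome))


def _chain_seq(genome, chrom, strand, chain_tx) -> str:
    return "".join(fetch(genome, chrom, s, e, strand) for s, e in chain_tx)


def _tx_coord(chain_tx, strand, gpos) -> int | None:
    """Transcript coordinate of genomic position ``gpos``, or None."""
    off = 0
    for s, e in chain_tx:
        if s <= gpos < e:
            return off + (gpos - s if strand == "+" else e - 1 - gpos)
        off += e - s
    return None


def read_gene_models(gtf_path) -> dict[str, GeneModel]:
    """Parse a GTF into single-isoform :class:`GeneModel` objects.

    Requires exon and CDS features carrying gene_id/transcript_id
    attributes. Multi-isoform genes are rejected — the reconstruction logic
    assumes one transcript per gene.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: dict[str, GeneModel] = {}
    by_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx = feat.attributes["transcript_id"][0]
        rec = by_tx.setdefault(
            tx,
            {
                "gene_id": feat.attributes["gene_id"][0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "cds": [],
            },
        )
        key = "exons" if feat.featuretype == "exon" else "cds"
        rec[key].append((feat.start - 1, feat.end))  # GTF -> half-open
    seen_genes: set[str] = set()
    for tx, rec in by_tx.items():
        gid = rec["gene_id"]
        if gid in seen_genes:
            raise ValueError(f"gene {gid} has multiple transcripts")
        seen_genes.add(gid)
        models[gid] = GeneModel(
            gene_id=gid,
            transcript_id=tx,
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=rec["exons"],
            cds=rec["cds"],
        )
    return models


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------


def translate_cds(seq: str) -> str:
    """Standard-code translation of ``seq`` up to the first stop codon."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate(to_stop=True))


# ---------------------------------------------------------------------------
# Altered transcripts
# ---------------------------------------------------------------------------


@dataclass
class AlteredTranscript:
    """A splice-variant transcript and its predicted translation product."""

    event_id: str
    gene_id: str
    variant: str  # 'SE_exclusion' | 'RI_inclusion'
    sequence: str
    protein: str
    frameshifted: bool
    premature_stop: bool
    start_lost: bool = False
    start_tx: int | None = None  # transcript coord of the canonical START


class ReconciliationError(ValueError):
    """Event coordinates do not match the gene model."""


def select_productive_events(events: pd.DataFrame) -> pd.DataFrame:
    """Keep the event classes expected to yield novel protein sequence.

    Skipped exons with *decreased* inclusion (the exclusion isoform gains
    abundance in the treated group) and retained introns with *increased*
    retention. All other types/directions are dropped. Adds a ``variant``
    column.
    """
    se = events[(events["event_type"] == "SE") & (events["delta_psi"] < 0)]
    ri = events[(events["event_type"] == "RI") & (events["delta_psi"] > 0)]
    se = se.assign(variant="SE_exclusion")
    ri = ri.assign(variant="RI_inclusion")
    return pd.concat([se, ri]).sort_index()


def reconstruct_transcript(event, gene_model: GeneModel, genome) -> AlteredTranscript:
    """Build the altered transcript for one productive event.

    ``event`` is a mapping (e.g. a DataFrame row) with rMATS-style
    coordinate fields. SE exclusion removes the cassette exon from the exon
    chain; RI inclusion merges the two flanking exons across the retained
    intron.
    """
    m = gene_model
    etype = event["event_type"]
    exons = list(m.exons)
    if etype == "SE":
        exon = (int(event["exonStart_0base"]), int(event["exonEnd"]))
        if exon not in exons:
            raise ReconciliationError(
                f"{m.gene_id}: skipped exon {exon} is not an annotated exon"
            )
        idx = exons.index(exon)
        if idx in (0, len(exons) - 1):
            raise ReconciliationError(
                f"{m.gene_id}: skipped exon {exon} is not internal"
            )
        new_exons = exons[:idx] + exons[idx + 1 :]
        changed = _cds_overlap(m.cds, exon)
        variant = "SE_exclusion"
    elif etype == "RI":
        from .splice_events import ri_intron_interval

        intron = ri_intron_interval(event)
        gaps = m.introns()
        if intron not in gaps:
            raise ReconciliationError(
                f"{m.gene_id}: retained intron {intron} does not match an "
                f"annotated intron (introns: {gaps})"
            )
        idx = gaps.index(intron)
        merged = (exons[idx][0], exons[idx + 1][1])
        new_exons = exons[:idx] + [merged] + exons[idx + 2 :]
        changed = (
            intron[1] - intron[0]
            if _within_cds_span(m, intron)
            else 0
        )
        variant = "RI_inclusion"
    else:
        raise ReconciliationError(f"unsupported productive event type {etype!r}")

    frameshifted = changed % 3 != 0
    chain_tx = new_exons if m.strand == "+" else new_exons[::-1]
    seq = _chain_seq(genome, m.chrom, m.strand, chain_tx)
    start_tx = _tx_coord(chain_tx, m.strand, m.canonical_start)
    alt = AlteredTranscript(
        event_id=str(event.get("event_id", event.get("ID", ""))),
        gene_id=m.gene_id,
        variant=variant,
        sequence=seq,
        protein="",
        frameshifted=frameshifted,
        premature_stop=False,
        start_lost=start_tx is None,
        start_tx=start_tx,
    )
    if start_tx is None:
        return alt
    alt.protein = translate_cds(seq[start_tx:])
    stop_tx = _tx_coord(chain_tx, m.strand, m.cds_last_base)
    if stop_tx is not None:
        expected_cds_len = stop_tx + 1 - start_tx
        alt.premature_stop = 3 * (len(alt.protein) + 1) < expected_cds_len
    else:
        alt.premature_stop = True
    return alt


def _cds_overlap(cds, interval) -> int:
    s, e = interval
    return sum(max(0, min(e, ce) - max(s, cs)) for cs, ce in cds)


def _within_cds_span(m: GeneModel, interval) -> bool:
    lo, hi = m.cds[0][0], m.cds[-1][1]
    return lo <= interval[0] and interval[1] <= hi


def translate_canonical(altered: AlteredTranscript, gene_model: GeneModel | None = None) -> str:
    """Protein from the annotated canonical START to the first stop.

    Returns the empty string when the START-containing exon was removed by
    the event (``start_lost``).
    """
    if altered.start_lost or altered.start_tx is None:
        return ""
    return translate_cds(altered.sequence[altered.start_tx :])


# ---------------------------------------------------------------------------
# Peptide digestion and novelty
# ---------------------------------------------------------------------------


def digest_kmers(protein: str, k_min: int = 8, k_max: int = 14) -> set[str]:
    """All unique substrings of length k_min..k_max (MHC-I ligand lengths)."""
    if k_min < 1 or k_max < k_min:
        raise ValueError("require 1 <= k_min <= k_max")
    out: set[str] = set()
    n = len(protein)
    for k in range(k_min, k_max + 1):
        for i in range(n - k + 1):
            out.add(protein[i : i + k])
    return out


@dataclass
class PeptideCandidate:
    peptide: str
    source_event_id: str
    source_span: tuple[int, int] | None = None  # aa coords in source protein
    novel: bool = False
    binding: dict = field(default_factory=dict)


def _join_proteome(proteome) -> str:
    if isinstance(proteome, dict):
        seqs = proteome.values()
    else:
        seqs = list(proteome)
    return "|".join(seqs)


def novelty_filter(peptides, proteome, source_event_id: str = "") -> list[PeptideCandidate]:
    """Mark each peptide as novel iff absent from every canonical protein."""
    joined = _join_proteome(proteome)
    out = []
    for pep in sorted(set(peptides)):
        out.append(
            PeptideCandidate(
                peptide=pep,
                source_event_id=source_event_id,
                novel=pep not in joined,
            )
        )
    return out


def find_neopeptide_candidates(
    events: pd.DataFrame,
    gene_models: dict[str, GeneModel],
    genome,
    proteome,
    k_min: int = 8,
    k_max: int = 14,
) -> pd.DataFrame:
    """End-to-end: productive events -> unique novel 8–14mer candidates.

    Returns one row per unique peptide with provenance (comma-joined event
    ids when a peptide arises from several events). Only novel peptides —
    absent as substrings from the canonical proteome — are returned.
    """
    productive = select_productive_events(events)
    joined = _join_proteome(proteome)
    rows: dict[str, dict] = {}
    for _, ev in productive.iterrows():
        model = gene_models[ev["gene_id"]]
        alt = reconstruct_transcript(ev, model, genome)
        if alt.start_lost or not alt.protein:
            continue
        for pep in digest_kmers(alt.protein, k_min, k_max):
            if pep in joined:
                continue
            rec = rows.setdefault(
                pep,
                {
                    "peptide": pep,
                    "events": set(),
                    "variants": set(),
                    "genes": set(),
                },
            )
            rec["events"].add(str(ev["event_id"]))
            rec["variants"].add(alt.variant)
            rec["genes"].add(model.gene_id)
    out = pd.DataFrame(
        [
            {
                "peptide": r["peptide"],
                "length": len(r["peptide"]),
                "event_ids": ",".join(sorted(r["events"])),
                "variants": ",".join(sorted(r["variants"])),
                "gene_ids": ",".join(sorted(r["genes"])),
                "novel": True,
            }
            for r in rows.values()
        ],
        columns=["peptide", "length", "event_ids", "variants", "gene_ids", "novel"],
    )
    return out.sort_values("peptide").reset_index(drop=True)


# ---------------------------------------------------------------------------
# MHC-I binding interface
# ---------------------------------------------------------------------------

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

# Toy 9-mer anchor matrix loosely shaped like HLA-A*02:01 preferences
# (hydrophobic P2 and P9 anchors). Exists only so the binding stage is
# testable offline; it is NOT a trained predictor.
_TOY_ANCHORS = {1: {"L": 3.0, "M": 2.5, "I": 2.0}, 8: {"V": 3.0, "L": 2.5, "I": 2.0}}


def toy_score(peptide: str) -> float:
    """Anchor-matrix score for a 9-mer (higher = better predicted binding)."""
    if len(peptide) != 9:
        raise ValueError("toy scorer handles 9-mers only")
    return sum(_TOY_ANCHORS[p].get(peptide[p], 0.0) for p in _TOY_ANCHORS)


def _sample_background(proteome, n: int, k: int, rng: np.random.Generator) -> list[str]:
    seqs = [s for s in (_join_proteome(proteome)).split("|") if len(s) >= k]
    if not seqs:
        raise ValueError("proteome has no protein of length >= k")
    out = []
    for _ in range(n):
        s = seqs[rng.integers(len(seqs))]
        i = int(rng.integers(len(s) - k + 1))
        out.append(s[i : i + k])
    return out


def parse_netmhcpan(path) -> pd.DataFrame:
    """Parse NetMHCpan v4.1-style whitespace-tabular output.

    Expects a header line containing at least ``Peptide`` and a rank column
    (``%Rank``/``%Rank_EL``/``EL_Rank``/``Rank``); lines starting with '#'
    or made of dashes are skipped. Returns columns peptide, allele (if
    present), score (if present), percent_rank.
    """
    header = None
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#") or set(line) <= {"-", " "}:
                continue
            parts = line.split()
            if header is None:
                header = parts
                continue
            if len(parts) < len(header):
                raise ValueError(
                    f"{path}: line {lineno} has {len(parts)} fields, "
                    f"expected >= {len(header)}: {line!r}"
                )
            records.append(parts[: len(header)])
    if header is None:
        raise ValueError(f"{path}: no header line found")
    df = pd.DataFrame(records, columns=header)
    rank_col = next(
        (c for c in ("%Rank_EL", "%Rank", "EL_Rank", "Rank") if c in df.columns), None
    )
    if "Peptide" not in df.columns or rank_col is None:
        raise ValueError(
            f"{path}: header must contain 'Peptide' and a rank column, got {header}"
        )
    out = pd.DataFrame({"peptide": df["Peptide"]})
    for src, dst in (("MHC", "allele"), ("HLA", "allele"), ("Score", "score"),
                     ("Score_EL", "score")):
        if src in df.columns and dst not in out.columns:
            out[dst] = df[src]
    out["percent_rank"] = df[rank_col].astype(float)
    if "score" in out.columns:
        out["score"] = out["score"].astype(float)
    return out


def predict_binding(
    candidates: pd.DataFrame,
    allele: str = "HLA-A*02:01",
    backend: str = "toy",
    netmhcpan_table=None,
    proteome=None,
    n_background: int = 1000,
    seed: int = 0,
    strong_rank: float = 0.5,
    weak_rank: float = 2.0,
) -> pd.DataFrame:
    """Attach binding records (percent rank, binder class) to candidates.

    ``backend='netmhcpan'`` joins a parsed NetMHCpan v4.1 output table on
    the peptide sequence. ``backend='toy'`` scores 9-mers with the anchor
    matrix and converts scores to a percent rank against ``n_background``
    peptides sampled from the canonical proteome. Binder classes follow the
    NetMHCpan convention: strong <= ``strong_rank`` %, weak <= ``weak_rank`` %.
    """
    out = candidates.copy()
    out["allele"] = allele
    if backend == "netmhcpan":
        table = (
            parse_netmhcpan(netmhcpan_table)
            if not isinstance(netmhcpan_table, pd.DataFrame)
            else netmhcpan_table
        )
        ranks = table.set_index("peptide")["percent_rank"]
        out["percent_rank"] = out["peptide"].map(ranks)
    elif backend == "toy":
        if proteome is None:
            raise ValueError("toy backend needs a proteome for the background")
        rng = np.random.default_rng(seed)
        bg = np.array([toy_score(p) for p in _sample_background(proteome, n_background, 9, rng)])
        ranks = []
        for pep in out["peptide"]:
            if len(pep) != 9:
                ranks.append(np.nan)
                continue
            s = toy_score(pep)
            ranks.append(100.0 * (1 + int((bg > s).sum())) / (1 + len(bg)))
        out["percent_rank"] = ranks
    else:
        raise ValueError(f"unknown backend {backend!r}")
    out["binder_class"] = np.select(
        [out["percent_rank"] <= strong_rank, out["percent_rank"] <= weak_rank],
        ["strong", "weak"],
        default="non-binder",
    )
    out.loc[out["percent_rank"].isna(), "binder_class"] = "unscored"
    return out


# ---------------------------------------------------------------------------
# Sequence logo statistics
# ---------------------------------------------------------------------------


def peptide_logo_matrix(peptides) -> tuple[pd.DataFrame, np.ndarray]:
    """Position frequency matrix and per-position information content.

    All peptides must be 9-mers. Information content is log2(20) minus the
    Shannon entropy of the residue distribution at each position.
    """
    peps = list(peptides)
    if not peps:
        raise ValueError("no peptides")
    if any(len(p) != len(peps[0]) for p in peps):
        raise ValueError("mixed peptide lengths")
    L = len(peps[0])
    counts = np.zeros((L, len(AA_ORDER)))
    idx = {a: i for i, a in enumerate(AA_ORDER)}
    for p in peps:
        for pos, aa in enumerate(p):
            counts[pos, idx[aa]] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    ic = np.log2(len(AA_ORDER)) + plogp.sum(axis=1)
    return pd.DataFrame(freq, columns=list(AA_ORDER)), ic


def write_candidates_fasta(candidates: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, row in candidates.iterrows():
            fh.write(
                f">{row['peptide']} events={row['event_ids']} "
                f"variants={row['variants']} genes={row['gene_ids']}\n"
                f"{row['peptide']}\n"
            )
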