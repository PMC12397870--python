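"""ORF strata construction from a genome FASTA and GTF annotation.

Builds exhaustive (and optionally RNA-expression-informed) polypeptide
databases stratified by genomic origin: CDS main ORF, CDS off-frame,
5'-UTR, 3'-UTR, intron, intergenic and lncRNA.  ORFs are scanned in all
three frames of each feature sequence (both strands for strandless
intergenic regions), starting at ATG/CTG/GTG/ATC/ACG, one longest ORF per
stop codon, at least 8 amino acids long.  Codons containing IUPAC
ambiguity letters are translated when every expansion agrees on one
residue (or all are stops); otherwise they become X.

Coordinate conventions: GTF is 1-based inclusive and converted at the
parser boundary; everything internal is 0-based half-open.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import edlib
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

START_CODONS = ("ATG", "CTG", "GTG", "ATC", "ACG")
MIN_ORF_AA = 8
MIN_PROTEIN_AA = 5
STOP = "*"

STRATA = (
    "cds_main", "cds_offframe", "utr5", "utr3", "intron", "intergenic", "lncRNA",
)


@dataclass(frozen=True)
class GenomicFeature:
    """An annotation interval, 0-based half-open, on one strand."""

    chrom: str
    start: int
    end: int
    strand: str  # "+", "-" or "." (strandless intergenic)
    feature_type: str
    transcript_id: str = ""
    gene_id: str = ""
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end in {self}")


@dataclass(frozen=True)
class OpenReadingFrame:
    """A translated ORF product labelled with its origin stratum."""

    orf_id: str
    stratum: str
    nt_seq: str
    aa_seq: str
    frame: int = 0  # six-frame index (0-2 forward, 3-5 reverse) for main-ORF tagging
    cds_overlap_class: str = "none"  # none | frameshift | in_frame
    parent_transcript: str = ""
    parent_gene: str = ""
    has_stop: bool = True


class GTFParseError(ValueError):
    pass


# --- codon machinery -------------------------------------------------------

def _expand_codon(codon: str) -> list[str]:
    out = [""]
    for base in codon:
        try:
            choices = ambiguous_dna_values[base]
        except KeyError:
            raise ValueError(f"illegal nucleotide {base!r}") from None
        out = [prefix + c for prefix in out for c in choices]
    return out

_FORWARD = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)


def _translate_codon(codon: str) -> str:
    """One residue, ``*`` for a definite stop, X when expansions disagree."""
    if codon in _FORWARD:
        return _FORWARD[codon]
    if codon in _STOPS:
        return STOP
    residues = set()
    for exp in _expand_codon(codon):
        residues.add(STOP if exp in _STOPS else _FORWARD[exp])
    if len(residues) == 1:
        return residues.pop()
    return "X"


def _is_stop_codon(codon: str) -> bool:
    return _translate_codon(codon) == STOP


def translate(nt_seq: str) -> str:
    """Translate with fuzzy-codon handling; stops rendered as ``*``."""
    nt_seq = nt_seq.upper()
    if len(nt_seq) % 3:
        logger.warning("dropping trailing partial codon (%d nt)", len(nt_seq) % 3)
        nt_seq = nt_seq[: len(nt_seq) - len(nt_seq) % 3]
    return "".join(
        _translate_codon(nt_seq[pos : pos + 3]) for pos in range(0, len(nt_seq), 3)
    )


def reverse_complement(nt_seq: str) -> str:
    return str(Seq(nt_seq).reverse_complement())


def six_frame_translations(nt_seq: str) -> list[str]:
    """Frames 0-2: forward offsets 0..2; frames 3-5: reverse-complement offsets."""
    frames = []
    for template in (nt_seq, reverse_complement(nt_seq)):
        for offset in range(3):
            frames.append(translate(template[offset:]))
    return frames


# --- GTF parsing -----------------------------------------------------------

def _parse_attributes(raw: str) -> dict:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_annotation(
    gtf_stream, chrom_lengths: Optional[dict] = None
) -> list[GenomicFeature]:
    """Parse a GENCODE-dialect GTF into :class:`GenomicFeature` records.

    Emits per-transcript exon/CDS/UTR features, derives introns as gaps
    between consecutive exons, classifies plain ``UTR`` features as 5' or
    3' by their position relative to the transcript's CDS, and — when
    ``chrom_lengths`` is given — adds strandless intergenic features as
    the chromosome complement of gene spans.  lncRNA transcripts are
    flagged from the gene_type/transcript_type attribute.
    """
    if isinstance(gtf_stream, str):
        gtf_stream = iter(gtf_stream.splitlines())
    features: list[GenomicFeature] = []
    for line_no, line in enumerate(gtf_stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GTFParseError(
                f"line {line_no}: expected 9 tab-separated fields, got {len(fields)}"
            )
        chrom, _source, ftype, start, end, _score, strand, _frame, raw_attrs = fields
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise GTFParseError(f"line {line_no}: non-integer coordinates") from None
        if start_i < 1 or end_i < start_i:
            raise GTFParseError(f"line {line_no}: invalid coordinate range")
        attrs = _parse_attributes(raw_attrs)
        if ftype != "gene" and "transcript_id" not in attrs:
            logger.warning("line %d: missing transcript_id, record rejected", line_no)
            continue
        biotype = attrs.get("transcript_type") or attrs.get("gene_type") or ""
        features.append(
            GenomicFeature(
                chrom=chrom,
                start=start_i - 1,  # GTF 1-based inclusive -> 0-based half-open
                end=end_i,
                strand=strand,
                feature_type=ftype,
                transcript_id=attrs.get("transcript_id", ""),
                gene_id=attrs.get("gene_id", ""),
                biotype=biotype,
            )
        )
    features.extend(_derive_introns(features))
    features = _classify_utrs(features)
    if chrom_lengths is not None:
        features.extend(_derive_intergenic(features, chrom_lengths))
    return features


def _by_transcript(features, ftype):
    grouped = defaultdict(list)
    for f in features:
        if f.feature_type == ftype and f.transcript_id:
            grouped[f.transcript_id].append(f)
    for fs in grouped.values():
        fs.sort(key=lambda f: f.start)
    return grouped


def _derive_introns(features: Sequence[GenomicFeature]) -> list[GenomicFeature]:
    introns = []
    for tid, exons in _by_transcript(features, "exon").items():
        for left, right in zip(exons, exons[1:]):
            if right.start > left.end:
                introns.append(
                    replace(left, start=left.end, end=right.start, feature_type="intron")
                )
    return introns


def _classify_utrs(features: Sequence[GenomicFeature]) -> list[GenomicFeature]:
    """Rename plain GTF ``UTR`` features to UTR5/UTR3 relative to the CDS."""
    cds = _by_transcript(features, "CDS")
    out = []
    for f in features:
        ftype = f.feature_type
        if ftype in {"five_prime_utr", "five_prime_UTR"}:
            ftype = "UTR5"
        elif ftype in {"three_prime_utr", "three_prime_UTR"}:
            ftype = "UTR3"
        elif ftype == "UTR":
            spans = cds.get(f.transcript_id)
            if not spans:
                logger.warning(
                    "UTR feature of %s has no CDS to orient against", f.transcript_id
                )
                out.append(f)
                continue
            upstream = f.end <= spans[0].start
            if f.strand == "-":
                ftype = "UTR3" if upstream else "UTR5"
            else:
                ftype = "UTR5" if upstream else "UTR3"
        out.append(replace(f, feature_type=ftype))
    return out


def _derive_intergenic(
    features: Sequence[GenomicFeature], chrom_lengths: dict
) -> list[GenomicFeature]:
    spans = defaultdict(list)
    for f in features:
        if f.feature_type in {"gene", "transcript"}:
            spans[f.chrom].append((f.start, f.end))
    out = []
    for chrom, length in chrom_lengths.items():
        merged = []
        for start, end in sorted(spans.get(chrom, [])):
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        cursor = 0
        for start, end in merged + [(length, length)]:
            if start > cursor:
                out.append(
                    GenomicFeature(chrom, cursor, start, ".", "intergenic")
                )
            cursor = max(cursor, end)
    return out


# --- sequence extraction ---------------------------------------------------

def extract_feature_sequence(
    feature: GenomicFeature | Sequence[GenomicFeature], genome: dict
) -> str:
    """Nucleotide sequence of a feature or multi-interval transcript.

    Minus-strand sequences are reverse-complemented; multi-interval input
    is spliced in transcription order (3'-most genomic interval first on
    the minus strand).
    """
    feats = [feature] if isinstance(feature, GenomicFeature) else sorted(
        feature, key=lambda f: f.start
    )
    parts = []
    for f in feats:
        try:
            chrom_seq = genome[f.chrom]
        except KeyError:
            raise ValueError(f"unknown chromosome {f.chrom!r} for {f}") from None
        if f.end > len(chrom_seq):
            raise ValueError(f"feature out of chromosome bounds: {f}")
        parts.append(chrom_seq[f.start : f.end])
    seq = "".join(parts)
    if feats[0].strand == "-":
        seq = reverse_complement(seq)
    return seq


def feature_position_map(
    feature: GenomicFeature | Sequence[GenomicFeature],
) -> list[int]:
    """Genomic position of every base of the extracted sequence, in reading order."""
    feats = [feature] if isinstance(feature, GenomicFeature) else sorted(
        feature, key=lambda f: f.start
    )
    positions = [pos for f in feats for pos in range(f.start, f.end)]
    if feats[0].strand == "-":
        positions.reverse()
    return positions


# --- ORF discovery ---------------------------------------------------------

@dataclass(frozen=True)
class ORFHit:
    """One ORF in a scanned sequence; start/end are 0-based nt offsets,
    end exclusive of the stop codon."""

    start: int
    end: int
    frame: int
    aa_seq: str
    has_stop: bool


def find_orfs(
    nt_seq: str,
    start_codons: Sequence[str] = START_CODONS,
    min_aa: int = MIN_ORF_AA,
    include_no_stop: bool = True,
) -> list[ORFHit]:
    """Longest ORF per stop codon in each of the three forward frames.

    For every stop codon the single ORF reported runs from the most
    upstream start codon (after the previous stop) to that stop.  ORFs
    reaching the 3' end without a stop are flagged ``has_stop=False`` and
    included by default.  Length is counted in amino acids excluding the
    stop.
    """
    nt_seq = nt_seq.upper()
    start_set = set(start_codons)
    hits = []
    for frame in range(3):
        first_start = None
        for pos in range(frame, len(nt_seq) - 2, 3):
            codon = nt_seq[pos : pos + 3]
            if _is_stop_codon(codon):
                if first_start is not None and (pos - first_start) // 3 >= min_aa:
                    hits.append(
                        ORFHit(
                            first_start, pos, frame,
                            translate(nt_seq[first_start:pos]), True,
                        )
                    )
                first_start = None
            elif first_start is None and codon in start_set:
                first_start = pos
        if include_no_stop and first_start is not None:
            end = first_start + 3 * ((len(nt_seq) - first_start) // 3)
            if (end - first_start) // 3 >= min_aa:
                hits.append(
                    ORFHit(
                        first_start, end, frame,
                        translate(nt_seq[first_start:end]), False,
                    )
                )
    return hits


# --- CDS overlap and main-ORF detection ------------------------------------

def classify_cds_overlap(
    orf_positions: Sequence[int], cds_positions: Sequence[int]
) -> str:
    """none / frameshift / in_frame for an ORF against a CDS.

    Both arguments list the genomic position of every base in reading
    order; a base's codon phase is its index mod 3.  ``in_frame`` requires
    every shared base to have matching phase (reading order included), a
    single-phase disagreement or opposite reading order is a frameshift.
    """
    orf_phase = {pos: idx % 3 for idx, pos in enumerate(orf_positions)}
    cds_phase = {pos: idx % 3 for idx, pos in enumerate(cds_positions)}
    shared = orf_phase.keys() & cds_phase.keys()
    if not shared:
        return "none"
    if all(orf_phase[p] == cds_phase[p] for p in shared):
        return "in_frame"
    return "frameshift"


def edit_distance(a: str, b: str) -> int:
    """Generalized Levenshtein distance (insert/delete/substitute)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def detect_main_orf(reference_protein: str, transcript_nt: str) -> int:
    """Six-frame index whose translation is closest to the reference protein.

    Ties break toward the lowest frame index (logged).
    """
    if len(transcript_nt) < 3:
        raise ValueError("transcript shorter than one codon")
    distances = [
        edit_distance(frame_aa.rstrip(STOP), reference_protein)
        for frame_aa in six_frame_translations(transcript_nt)
    ]
    best = min(distances)
    winners = [idx for idx, d in enumerate(distances) if d == best]
    if len(winners) > 1:
        logger.info("main-ORF tie among frames %s; choosing %d", winners, winners[0])
    return winners[0]


# --- expression gating -----------------------------------------------------

def filter_expressed(
    expression: pd.DataFrame, threshold: float = 10, mode: str = "every"
) -> set[str]:
    """Transcripts with >= threshold counts in every biological replicate.

    ``expression`` has a transcript_id column (or index) and one column
    per replicate.  ``mode="any"`` relaxes to at least one replicate.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    table = expression
    if "transcript_id" in table.columns:
        table = table.set_index("transcript_id")
    passing = (
        (table >= threshold).all(axis=1)
        if mode == "every"
        else (table >= threshold).any(axis=1)
    )
    return set(table.index[passing])


# --- strata assembly -------------------------------------------------------

def _dedup_and_filter(orfs: list[OpenReadingFrame]) -> list[OpenReadingFrame]:
    """Drop exact (id, sequence) duplicates and products < 5 aa."""
    seen = set()
    out = []
    for orf in orfs:
        key = (orf.orf_id, orf.aa_seq)
        if key in seen or len(orf.aa_seq) < MIN_PROTEIN_AA:
            continue
        seen.add(key)
        out.append(orf)
    return out


def _scan_feature(
    seq, stratum, tid, gid, cds_pos_map, pos_map, min_aa
) -> list[OpenReadingFrame]:
    out = []
    for hit in find_orfs(seq, min_aa=min_aa):
        if cds_pos_map and pos_map:
            overlap = classify_cds_overlap(
                pos_map[hit.start : hit.end], cds_pos_map
            )
        else:
            overlap = "none"
        out.append(
            OpenReadingFrame(
                orf_id=f"{stratum}|{tid or gid or 'seq'}|{hit.frame}:{hit.start}",
                stratum=stratum,
                nt_seq=seq[hit.start : hit.end],
                aa_seq=hit.aa_seq.rstrip(STOP),
                frame=hit.frame,
                cds_overlap_class=overlap,
                parent_transcript=tid,
                parent_gene=gid,
                has_stop=hit.has_stop,
            )
        )
    return out


def build_strata(
    features: Sequence[GenomicFeature],
    genome: dict,
    expression: Optional[pd.DataFrame] = None,
    expression_threshold: float = 10,
    min_orf_aa: int = MIN_ORF_AA,
    reference_proteins: Optional[dict] = None,
) -> dict[str, list[OpenReadingFrame]]:
    """Assemble the stratum-labelled polypeptide database.

    Returns a dict stratum -> ORF products, deduplicated and filtered to
    >= 5 aa.  When an expression table is given, transcript-derived
    strata are restricted to expressed transcripts (intergenic regions,
    which have no transcript, are unaffected).  ``reference_proteins``
    maps transcript_id -> annotated protein for main-ORF frame tagging.
    """
    expressed = (
        None
        if expression is None
        else filter_expressed(expression, expression_threshold)
    )

    def tx_ok(tid: str) -> bool:
        if expressed is None:
            return True
        if tid not in expressed and tid not in set(expression.get("transcript_id", [])):
            logger.warning("transcript %s absent from expression table", tid)
        return tid in expressed

    gene_of = {
        f.transcript_id: f.gene_id for f in features if f.transcript_id
    }
    exons = _by_transcript(features, "exon")
    cds = _by_transcript(features, "CDS")
    utr5 = _by_transcript(features, "UTR5")
    utr3 = _by_transcript(features, "UTR3")
    introns = _by_transcript(features, "intron")
    lnc_tids = {
        f.transcript_id
        for f in features
        if f.feature_type == "transcript" and f.biotype == "lncRNA"
    }

    strata: dict[str, list[OpenReadingFrame]] = {s: [] for s in STRATA}

    for tid, parts in cds.items():
        if not tx_ok(tid):
            continue
        gid = gene_of.get(tid, "")
        seq = extract_feature_sequence(parts, genome)
        pos_map = feature_position_map(parts)
        aa = translate(seq).rstrip(STOP).replace("U", "X")
        frame = 0
        if reference_proteins and tid in reference_proteins:
            tx_seq = extract_feature_sequence(exons.get(tid, parts), genome)
            frame = detect_main_orf(reference_proteins[tid], tx_seq)
        strata["cds_main"].append(
            OpenReadingFrame(
                orf_id=f"cds_main|{tid}",
                stratum="cds_main",
                nt_seq=seq,
                aa_seq=aa,
                frame=frame,
                cds_overlap_class="in_frame",
                parent_transcript=tid,
                parent_gene=gid,
            )
        )
        # off-frame ORFs rescanned on the same spliced CDS sequence
        for orf in _scan_feature(
            seq, "cds_offframe", tid, gid, pos_map, pos_map, min_orf_aa
        ):
            if orf.cds_overlap_class == "frameshift":
                strata["cds_offframe"].append(orf)

    for stratum, grouped in (("utr5", utr5), ("utr3", utr3)):
        for tid, parts in grouped.items():
            if not tx_ok(tid):
                continue
            seq = extract_feature_sequence(parts, genome)
            pos_map = feature_position_map(parts)
            cds_map = feature_position_map(cds[tid]) if tid in cds else []
            strata[stratum].extend(
                _scan_feature(
                    seq, stratum, tid, gene_of.get(tid, ""), cds_map, pos_map,
                    min_orf_aa,
                )
            )

    for tid, parts in introns.items():
        if not tx_ok(tid):
            continue
        cds_map = feature_position_map(cds[tid]) if tid in cds else []
        for part in parts:  # each intron scanned separately
            seq = extract_feature_sequence(part, genome)
            pos_map = feature_position_map(part)
            strata["intron"].extend(
                _scan_feature(
                    seq, "intron", tid, gene_of.get(tid, ""), cds_map, pos_map,
                    min_orf_aa,
                )
            )

    for tid in lnc_tids:
        if not tx_ok(tid) or tid not in exons:
            continue
        seq = extract_feature_sequence(exons[tid], genome)
        strata["lncRNA"].extend(
            _scan_feature(
                seq, "lncRNA", tid, gene_of.get(tid, ""), [], [], min_orf_aa
            )
        )

    for f in features:
        if f.feature_type != "intergenic":
            continue
        fwd = extract_feature_sequence(replace(f, strand="+"), genome)
        for strand_label, seq in (("+", fwd), ("-", reverse_complement(fwd))):
            orfs = _scan_feature(
                seq, "intergenic", "", f"{f.chrom}:{f.start}-{f.end}({strand_label})",
                [], [], min_orf_aa,
            )
            strata["intergenic"].extend(orfs)

    return {s: _dedup_and_filter(orfs) for s, orfs in strata.items()}


def write_strata_fasta(strata: dict, directory) -> dict:
    """One protein FASTA per stratum; returns stratum -> path."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for stratum, orfs in strata.items():
        path = directory / f"{stratum}.fasta"
        with open(path, "w") as fh:
            for orf in orfs:
                header = "|".join(
                    [
                        orf.orf_id, orf.stratum, orf.parent_transcript or "-",
                        orf.parent_gene or "-", orf.cds_overlap_class,
                    ]
                )
                fh.write(f">{header}\n{orf.aa_seq}\n")
        paths[stratum] = path
    return paths
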