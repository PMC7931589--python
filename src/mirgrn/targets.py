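"""3'UTR inference and dual-predictor miRNA target prediction.

Stages, each exposed separately:

1. ``predict_utr`` — infer a 3'UTR from the region downstream of the stop
   codon using the AAUAAA polyadenylation consensus; the UTR ends at the
   final base of the closest signal hexamer.  If that UTR would exceed
   2,500 nt the secondary consensus AUUAAA is used instead; if both exceed
   the cap the shorter record is kept with a ``long`` flag.
2. ``seed_sites`` — canonical seed-match scan (8mer, 7mer-m8, 7mer-A1, 6mer)
   against exact Watson-Crick reverse complements of mature positions 2-7,
   extended by the position-8 match and the A opposite position 1;
   overlapping classifications resolve to the longest type.
3. ``duplex_align`` / ``hybrid_align`` — Smith-Waterman-style hybridization
   alignment of the mature (3'->5') against the UTR (5'->3') with a declared
   scoring scheme (WC +5, G:U wobble +1 outside the seed, mismatch -3, gap
   open -8, gap extend -2) and a dinucleotide stack-energy proxy.  In strict
   mode an alignment is retained only when score >= 80, energy <= -7
   kcal/mol, and the seed region (positions 2-8) is fully Watson-Crick
   paired without gaps.
4. ``consensus_targets`` — intersect the two predictors, requiring their
   seed-match coordinates to agree within 10 nt (a gene-level mode is
   available).
5. ``filter_expressed`` — keep targets whose gene reaches TPM >= 1 in the
   heart transcriptome of the species.

Coordinates are 0-based, half-open, with 0 = the first nt after the stop
codon; scanning is on the given (sense) strand only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .simulate import revcomp, _COMP

logger = logging.getLogger(__name__)

UTR_MAX = 2500
MAX_SCAN = 10000
SCORE_MIN = 80.0
ENERGY_MAX = -7.0
TPM_MIN = 1.0
CONSENSUS_MAX_GAP = 10

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}

# dinucleotide stack-energy proxy (kcal/mol) over maximal WC runs
STACK_GC = -3.3
STACK_AU = -0.9
STACK_MIXED = -2.1

MATCH = 5.0
WOBBLE_SCORE = 1.0
MISMATCH = -3.0
GAP_OPEN = -8.0
GAP_EXTEND = -2.0


# ---------------------------------------------------------------------------
# 3'UTR inference


@dataclass
class UTRRecord:
    gene: str
    source: str               # "annotated" | "predicted"
    sequence: str
    start: int                # offset downstream of stop codon (0-based)
    end: int                  # half-open; predicted UTRs end at the signal's last nt
    signal: str               # "AAUAAA" | "AUUAAA" | "none"
    long: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def predict_utr(
    downstream: str,
    *,
    gene: str = "",
    max_scan: int = MAX_SCAN,
    utr_max: int = UTR_MAX,
) -> UTRRecord | None:
    """Infer the 3'UTR from the sequence immediately 3' of the stop codon.

    Returns None when the sequence is empty or no signal hexamer occurs
    within ``max_scan`` nt (the gene is then excluded from prediction).
    """
    if not downstream:
        return None
    scan = downstream[:max_scan]
    ends = {}
    for signal in ("AAUAAA", "AUUAAA"):
        pos = scan.find(signal)
        if pos >= 0:
            ends[signal] = pos + 6
    if not ends:
        return None
    if "AAUAAA" in ends and ends["AAUAAA"] <= utr_max:
        chosen, long_flag = "AAUAAA", False
    elif "AUUAAA" in ends and ends["AUUAAA"] <= utr_max:
        chosen, long_flag = "AUUAAA", False
    else:
        chosen = min(ends, key=lambda s: (ends[s], s))
        long_flag = True
    end = ends[chosen]
    return UTRRecord(gene, "predicted", downstream[:end], 0, end, chosen, long_flag)


# ---------------------------------------------------------------------------
# Seed-type predictor


@dataclass(frozen=True)
class SeedSite:
    mirna: str
    gene: str
    site_type: str            # "8mer" | "7mer-m8" | "7mer-A1" | "6mer"
    core_start: int           # UTR position of the 6mer-core match (0-based)
    start: int                # full site span (half-open)
    end: int
    matched: str


def seed_sites(mature: str, utr: UTRRecord, *, mirna: str = "") -> list[SeedSite]:
    """All canonical seed-match sites of one mature sequence in one UTR.

    The 6mer core is the exact reverse complement of mature positions 2-7;
    the position-8 match is checked one base 5' of the core and the A1
    anchor one base 3' of it.  Each core occurrence yields exactly one site
    of the longest applicable type.
    """
    if len(mature) < 19:
        raise ValueError("mature sequence shorter than 19 nt")
    seq = utr.sequence
    if len(seq) < 6:
        return []
    core = revcomp(mature[1:7])
    m8_base = _COMP[mature[7]]
    sites = []
    p = seq.find(core)
    while p >= 0:
        m8 = p >= 1 and seq[p - 1] == m8_base
        a1 = p + 6 < len(seq) and seq[p + 6] == "A"
        if m8 and a1:
            stype, s, e = "8mer", p - 1, p + 7
        elif m8:
            stype, s, e = "7mer-m8", p - 1, p + 6
        elif a1:
            stype, s, e = "7mer-A1", p, p + 7
        else:
            stype, s, e = "6mer", p, p + 6
        sites.append(SeedSite(mirna, utr.gene, stype, p, s, e, seq[s:e]))
        p = seq.find(core, p + 1)
    return sites


# ---------------------------------------------------------------------------
# Hybridization predictor


@dataclass
class HybridAlignment:
    mirna: str
    gene: str
    score: float
    energy: float             # kcal/mol proxy; more negative = more stable
    pairs: list = field(default_factory=list)  # (utr_pos | None, mature_pos | None, state)
    seed_clean: bool = False
    utr_start: int = 0        # UTR span covered by the alignment
    utr_end: int = 0
    seed_span: tuple = (0, 0)  # UTR span aligned to mature positions 2-8

    def passes(self, score_min: float = SCORE_MIN, energy_max: float = ENERGY_MAX) -> bool:
        return self.score >= score_min and self.energy <= energy_max and self.seed_clean


def _pair_state(ub: str, mb: str, mature_pos: int) -> tuple[str, float]:
    if (ub, mb) in WC:
        return "WC", MATCH
    if (ub, mb) in WOBBLE:
        if 2 <= mature_pos <= 8:
            return "wobble", MISMATCH  # non-canonical in seed scores as mismatch
        return "wobble", WOBBLE_SCORE
    return "mismatch", MISMATCH


def duplex_align(
    mature: str,
    window: str,
    *,
    mirna: str = "",
    gene: str = "",
    window_offset: int = 0,
) -> HybridAlignment | None:
    """Best local duplex alignment of one mature against one UTR window.

    The mature is read 3'->5' against the window 5'->3' (antiparallel
    hybridization), with affine gaps charged -8 for the first gapped
    position and -2 for each extension.  Returns None when no positive-
    scoring alignment exists.
    """
    q = mature[::-1]                      # q[j] = mature position len - j (1-based)
    L = len(mature)
    t = window
    n, m = len(t), len(q)
    NEG = float("-inf")
    # M: ends in aligned pair; X: ends in target-consuming gap; Y: query-consuming gap
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptr: dict[tuple[int, int, str], tuple[int, int, str] | None] = {}
    best = (0.0, None)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            pos = L - (j - 1)              # 1-based mature position of q[j-1]
            _, s = _pair_state(t[i - 1], q[j - 1], pos)
            opts = [
                (0.0, None),
                (M[i - 1][j - 1], (i - 1, j - 1, "M")),
                (X[i - 1][j - 1], (i - 1, j - 1, "X")),
                (Y[i - 1][j - 1], (i - 1, j - 1, "Y")),
            ]
            prev_score, prev_ptr = max(opts, key=lambda o: o[0])
            M[i][j] = prev_score + s
            ptr[(i, j, "M")] = prev_ptr
            xo = [(M[i - 1][j] + GAP_OPEN, (i - 1, j, "M")),
                  (X[i - 1][j] + GAP_EXTEND, (i - 1, j, "X"))]
            X[i][j], ptr[(i, j, "X")] = max(xo, key=lambda o: o[0])
            yo = [(M[i][j - 1] + GAP_OPEN, (i, j - 1, "M")),
                  (Y[i][j - 1] + GAP_EXTEND, (i, j - 1, "Y"))]
            Y[i][j], ptr[(i, j, "Y")] = max(yo, key=lambda o: o[0])
            if M[i][j] > best[0]:
                best = (M[i][j], (i, j, "M"))
    if best[1] is None:
        return None

    pairs = []   # (utr_pos | None, mature_pos | None, state), 5'->3' on the UTR
    cell = best[1]
    while cell is not None:
        i, j, state = cell
        if state == "M":
            pos = L - (j - 1)
            st, _ = _pair_state(t[i - 1], q[j - 1], pos)
            pairs.append((window_offset + i - 1, pos, st))
        elif state == "X":
            pairs.append((window_offset + i - 1, None, "gap"))
        else:
            pairs.append((None, L - (j - 1), "gap"))
        cell = ptr[(i, j, state)]
    pairs.reverse()

    aligned_wc = {p for _, p, st in pairs if st == "WC"}
    seed_clean = all(pos in aligned_wc for pos in range(2, 9))
    energy = _stack_energy(pairs, mature)
    utr_positions = [u for u, _, st in pairs if u is not None]
    seed_utr = [u for u, p, st in pairs if u is not None and p is not None and 2 <= p <= 8]
    return HybridAlignment(
        mirna, gene, best[0], energy, pairs, seed_clean,
        utr_start=min(utr_positions), utr_end=max(utr_positions) + 1,
        seed_span=(min(seed_utr), max(seed_utr) + 1) if seed_utr else (0, 0),
    )


def _stack_energy(pairs, mature: str) -> float:
    """Stack-energy proxy over maximal runs of contiguous WC pairs.

    A run is a stretch of consecutive alignment columns that are WC-paired
    with both strands advancing by one (no gaps, no wobbles).  Each adjacent
    stacked pair contributes -3.3 (both pairs G:C), -0.9 (both A:U) or -2.1
    (mixed) kcal/mol; isolated pairs contribute nothing.
    """

    def pair_class(mature_pos: int) -> str:
        # a WC pair is G:C or A:U; classify from the mature base
        return "GC" if mature[mature_pos - 1] in "GC" else "AU"

    energy = 0.0
    prev: tuple[int, int] | None = None
    for u, p, st in pairs:
        if st == "WC" and u is not None and p is not None:
            if prev is not None and u == prev[0] + 1 and p == prev[1] - 1:
                a, b = pair_class(prev[1]), pair_class(p)
                if a == b == "GC":
                    energy += STACK_GC
                elif a == b == "AU":
                    energy += STACK_AU
                else:
                    energy += STACK_MIXED
            prev = (u, p)
        else:
            prev = None
    return energy


def hybrid_align(
    mature: str,
    window: str,
    *,
    mirna: str = "",
    gene: str = "",
    window_offset: int = 0,
    score_min: float = SCORE_MIN,
    energy_max: float = ENERGY_MAX,
) -> list[HybridAlignment]:
    """Strict-mode hybridization: best duplex alignments that pass all three
    retention rules (score, energy, clean Watson-Crick seed)."""
    if len(window) < len(mature):
        return []
    aln = duplex_align(mature, window, mirna=mirna, gene=gene, window_offset=window_offset)
    if aln is not None and aln.passes(score_min, energy_max):
        return [aln]
    return []


# ---------------------------------------------------------------------------
# Consensus and expression filter


@dataclass
class TargetInteraction:
    family: str
    species_gene: str
    ref_gene: str = ""
    species: tuple = ()
    evidence: str = "both"
    validated: bool = False
    validated_source: str = ""


def consensus_targets(
    seed_by_pair: dict,
    hybrid_by_pair: dict,
    *,
    max_gap: int = CONSENSUS_MAX_GAP,
    mode: str = "positional",
) -> list[tuple[str, str, SeedSite, HybridAlignment]]:
    """Intersect seed-type and hybridization predictions.

    ``seed_by_pair`` / ``hybrid_by_pair`` map (mirna, gene) to site lists.
    In positional mode a pair is kept when some seed site and some passing
    hybrid alignment have seed-match coordinates within ``max_gap`` nt of
    each other; in gene mode agreement at the gene level suffices.  The
    result is a subset of both predictors by construction.
    """
    if mode not in ("positional", "gene"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    kept = []
    for key in seed_by_pair:
        if key not in hybrid_by_pair:
            continue
        sites, hybrids = seed_by_pair[key], hybrid_by_pair[key]
        if not sites or not hybrids:
            continue
        found = None
        for s in sites:
            for h in hybrids:
                if mode == "gene":
                    found = (s, h)
                    break
                a0, a1 = s.core_start, s.core_start + 6
                b0, b1 = h.seed_span
                gap = max(b0 - a1, a0 - b1, 0)
                if gap <= max_gap:
                    found = (s, h)
                    break
            if found:
                break
        if found:
            kept.append((key[0], key[1], found[0], found[1]))
    return kept


def filter_expressed(
    interactions: pd.DataFrame,
    tpm: dict[str, float],
    threshold: float = TPM_MIN,
) -> pd.DataFrame:
    """Keep interactions whose target gene reaches TPM >= threshold.

    Genes absent from the TPM table are dropped and logged; TPM exactly at
    the threshold is kept.
    """
    keep = []
    missing = 0
    for _, row in interactions.iterrows():
        gene = row["gene"]
        if gene not in tpm:
            missing += 1
            continue
        keep.append(tpm[gene] >= threshold)
    if missing:
        logger.warning("%d interactions dropped: gene missing from TPM table", missing)
    present = interactions[interactions["gene"].map(lambda g: g in tpm)]
    return present[[tpm[g] >= threshold for g in present["gene"]]]


# ---------------------------------------------------------------------------
# Per-species prediction driver


def predict_targets_for_species(
    matures: dict[str, str],
    transcripts: dict[str, tuple[str, int]],
    tpm: dict[str, float],
    *,
    max_scan: int = MAX_SCAN,
    utr_max: int = UTR_MAX,
    score_min: float = SCORE_MIN,
    energy_max: float = ENERGY_MAX,
    tpm_min: float = TPM_MIN,
    max_gap: int = CONSENSUS_MAX_GAP,
    consensus_mode: str = "positional",
) -> dict:
    """Run UTR inference, both predictors, consensus and the expression
    filter for one species.

    ``matures`` maps miRNA id -> mature sequence; ``transcripts`` maps gene
    -> (transcript sequence, stop-codon offset).  The hybridization scan is
    anchored at 6mer seed-core matches: in strict mode any passing duplex
    must have positions 2-8 fully WC-paired, so every admissible site
    contains an exact core match and anchoring loses nothing.

    Returns a dict with utrs, seed site/hybrid tables, consensus and
    filtered interaction DataFrames, and per-rule drop counts.
    """
    utrs: dict[str, UTRRecord] = {}
    for gene, (seq, stop) in transcripts.items():
        downstream = seq[stop + 3:]
        utr = predict_utr(downstream, gene=gene, max_scan=max_scan, utr_max=utr_max)
        if utr is not None:
            utrs[gene] = utr

    seed_by_pair: dict[tuple[str, str], list[SeedSite]] = {}
    hybrid_by_pair: dict[tuple[str, str], list[HybridAlignment]] = {}
    for mid, mature in matures.items():
        L = len(mature)
        for gene, utr in utrs.items():
            sites = seed_sites(mature, utr, mirna=mid)
            if not sites:
                continue
            seed_by_pair[(mid, gene)] = sites
            hybrids = []
            for s in sites:
                lo = max(0, s.core_start - (L - 7) - 6)
                hi = min(len(utr.sequence), s.core_start + 8 + 6)
                hybrids.extend(
                    hybrid_align(
                        mature, utr.sequence[lo:hi], mirna=mid, gene=gene,
                        window_offset=lo, score_min=score_min, energy_max=energy_max,
                    )
                )
            if hybrids:
                hybrid_by_pair[(mid, gene)] = hybrids

    consensus = consensus_targets(
        seed_by_pair, hybrid_by_pair, max_gap=max_gap, mode=consensus_mode
    )
    cons_df = pd.DataFrame(
        [{"mirna": m, "gene": g, "site_type": s.site_type, "core_start": s.core_start,
          "hybrid_score": h.score, "hybrid_energy": h.energy}
         for m, g, s, h in consensus],
        columns=["mirna", "gene", "site_type", "core_start", "hybrid_score", "hybrid_energy"],
    )
    filtered = filter_expressed(cons_df, tpm, threshold=tpm_min)
    return {
        "utrs": utrs,
        "seed_sites": seed_by_pair,
        "hybrids": hybrid_by_pair,
        "consensus": cons_df,
        "filtered": filtered.reset_index(drop=True),
        "counts": {
            "genes_with_utr": len(utrs),
            "pairs_with_seed_sites": len(seed_by_pair),
            "pairs_with_passing_hybrids": len(hybrid_by_pair),
            "consensus_pairs": len(cons_df),
            "expressed_pairs": len(filtered),
            "dropped_by_expression_filter": len(cons_df) - len(filtered),
        },
    }
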