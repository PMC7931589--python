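"""Synthetic heart-miRNome simulator with planted ground truth.

Generates every input the comparative pipeline consumes — per-species miRNA
precursor/mature catalogs, a family reference catalog with ages, a locus x
species read-count matrix, per-species transcript sets with plantable 3'UTRs,
TPM tables, an ortholog map, a STRING-like scored interaction table around a
heart-kernel gene set — together with a ground-truth ledger recording what was
planted (family conservation labels, target-site coordinates, interaction
strata, the per-group regulatory-network edge set expected to survive all
downstream filters).

Structure emulated from the study system:

* miRNA families share an identical seed (mature positions 2-8) held fixed
  while member precursors accumulate substitutions outside the seed;
* conserved families are expressed in every vertebrate group, group-specific
  families only in one group, with conserved families drawn at a higher
  log-scale expression mean;
* synthetic genes carry a single AAUAAA polyadenylation signal downstream of
  the stop codon, with full-length Watson-Crick target sites (containing a
  perfect 8mer) planted between stop codon and signal;
* the interaction table is stratified into edges that pass the score filter
  and touch the kernel, edges that fail the score rule, and passing edges
  disconnected from the kernel.

Randomness: one root seed; each generator stage draws from its own stream
derived as ``SeedSequence(entropy=root_seed, spawn_key=(stage_index,))`` with
stage indices catalog=0, counts=1, genes=2, ppi=3.  Identical seed and
parameters therefore give byte-identical outputs regardless of which stages
are run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

_STAGE = {"catalog": 0, "counts": 1, "genes": 2, "ppi": 3}

_BASES = np.array(list("ACGU"))
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}

DEFAULT_KERNEL = (
    "GATA4", "NKX2-5", "TBX5", "MEF2C", "SRF", "HAND1", "HAND2", "SMAD1",
)

#: Vertebrate group structure of the emulated study: 20 species in five groups.
DEFAULT_GROUPS = (
    ("fishes", 6),
    ("amphibians", 2),
    ("reptiles", 1),
    ("birds", 2),
    ("mammals", 9),
)


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE[stage],)))


def _random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


@dataclass
class SimulationParams:
    """Knobs of the simulator; defaults are the emulated study conditions."""

    seed: int = 0
    groups: tuple = DEFAULT_GROUPS
    n_conserved_families: int = 54
    n_specific_per_group: int = 10
    loci_per_family: int = 2
    precursor_len: tuple = (60, 90)
    mature_len: tuple = (20, 23)
    subst_rate: float = 0.02
    expr_logmean_conserved: float = 9.0
    expr_logmean_specific: float = 7.0
    expr_logsd: float = 1.0
    dropout_prob: float = 0.05
    n_genes: int = 500
    sites_per_mirna: int = 3
    utr_signal_offset_range: tuple = (150, 400)
    ppi_n_edges: int = 600
    kernel_genes: tuple = DEFAULT_KERNEL
    include_decoy_auuaaa: bool = False
    emit_secondary_reference: bool = False

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        labels = [g for g, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        for g, n in self.groups:
            if n < 1:
                raise ValueError(f"group {g!r} has zero species")
        if not (0.0 <= self.subst_rate <= 0.3):
            raise ValueError("subst_rate must be in [0, 0.3]")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.expr_logmean_conserved < self.expr_logmean_specific:
            raise ValueError("conserved log-mean must be >= specific log-mean")
        if self.loci_per_family < 1:
            raise ValueError("loci_per_family must be >= 1")
        for name in ("n_conserved_families", "n_specific_per_group", "n_genes",
                     "sites_per_mirna", "ppi_n_edges"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.kernel_genes:
            raise ValueError("kernel_genes must be nonempty")

    @property
    def species_by_group(self) -> dict[str, list[str]]:
        return {g: [f"{g}_{i + 1}" for i in range(n)] for g, n in self.groups}

    @property
    def all_species(self) -> list[str]:
        return [s for sp in self.species_by_group.values() for s in sp]


@dataclass
class FamilySpec:
    name: str
    label: str                    # "conserved" | "group_specific:<group>"
    precursor: str                # ancestral reference precursor
    mature_start: int
    mature_len: int
    age_mya: int
    species: list[str]            # species carrying the family

    @property
    def mature(self) -> str:
        return self.precursor[self.mature_start:self.mature_start + self.mature_len]

    @property
    def seed(self) -> str:
        """Seed = mature positions 2-8 (1-based), held invariant in members."""
        return self.mature[1:8]

    @property
    def site_seq(self) -> str:
        """Planted target site: full WC complement of mature 2..L plus an A
        opposite position 1 — contains a perfect 8mer at its 3' end."""
        return revcomp(self.mature[1:]) + "A"


@dataclass
class Member:
    locus_id: str
    species: str
    family: str
    precursor: str
    mature: str
    arm: str = "5p"


@dataclass
class Catalog:
    params: SimulationParams
    families: list[FamilySpec]
    members: list[Member]


@dataclass
class GroundTruthLedger:
    """Everything the simulator planted, for recovery testing downstream."""

    labels: dict = field(default_factory=dict)
    family_species: dict = field(default_factory=dict)
    family_age: dict = field(default_factory=dict)
    members: list = field(default_factory=list)
    groups: dict = field(default_factory=dict)
    gene_roles: dict = field(default_factory=dict)
    utr_boundaries: dict = field(default_factory=dict)   # gene -> [0, end)
    sites: dict = field(default_factory=dict)            # species -> gene -> [(family, start, end)]
    planted_pairs: list = field(default_factory=list)    # {family, gene, kind, species}
    ppi_strata: list = field(default_factory=list)
    planted_grn: dict = field(default_factory=dict)      # group -> {ppi, mir_target}

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Stage 1: miRNA catalog


def generate_catalog(params: SimulationParams) -> tuple[Catalog, GroundTruthLedger]:
    """Plant conserved and group-specific miRNA families.

    Conserved families get one or more loci in every species of every group;
    group-specific families only in the species of their group.  All members
    of a family share the ancestral seed exactly; substitutions are drawn
    uniformly on non-seed precursor positions at ``subst_rate`` per site and
    always change the base.
    """
    params.validate()
    rng = _stage_rng(params.seed, "catalog")
    species_by_group = params.species_by_group

    ledger = GroundTruthLedger(groups={g: list(sp) for g, sp in species_by_group.items()})

    specs: list[tuple[str, str, list[str]]] = []
    for i in range(params.n_conserved_families):
        specs.append((f"mir-C{i + 1:03d}", "conserved", params.all_species))
    for g, sp in species_by_group.items():
        for i in range(params.n_specific_per_group):
            specs.append((f"mir-{g}-S{i + 1:02d}", f"group_specific:{g}", list(sp)))

    seen_seeds: set[str] = set()
    families: list[FamilySpec] = []
    for name, label, sp_list in specs:
        for _ in range(1000):
            plen = int(rng.integers(params.precursor_len[0], params.precursor_len[1] + 1))
            mlen = int(rng.integers(params.mature_len[0], params.mature_len[1] + 1))
            mstart = int(rng.integers(8, 13))
            precursor = _random_rna(rng, plen)
            fam = FamilySpec(name, label, precursor, mstart, mlen, 0, list(sp_list))
            # keep seeds unique across families and planted sites free of
            # polyadenylation hexamers (they would truncate a planted UTR)
            if fam.seed in seen_seeds:
                continue
            if "AAUAAA" in fam.site_seq or "AUUAAA" in fam.site_seq:
                continue
            seen_seeds.add(fam.seed)
            break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("failed to draw an admissible family sequence")
        fam.age_mya = int(rng.integers(400, 691)) if label == "conserved" else int(rng.integers(20, 351))
        families.append(fam)

    members: list[Member] = []
    for fam in families:
        seed_span = range(fam.mature_start + 1, fam.mature_start + 8)
        for sp in fam.species:
            for j in range(params.loci_per_family):
                prec = list(fam.precursor)
                if params.subst_rate > 0:
                    for pos in range(len(prec)):
                        if pos in seed_span:
                            continue
                        if rng.random() < params.subst_rate:
                            others = [b for b in "ACGU" if b != prec[pos]]
                            prec[pos] = others[int(rng.integers(0, 3))]
                prec_s = "".join(prec)
                mature = prec_s[fam.mature_start:fam.mature_start + fam.mature_len]
                members.append(Member(f"{sp}|{fam.name}|{j + 1}", sp, fam.name, prec_s, mature))

    for fam in families:
        ledger.labels[fam.name] = fam.label
        ledger.family_species[fam.name] = list(fam.species)
        ledger.family_age[fam.name] = fam.age_mya
    ledger.members = [
        {"locus_id": m.locus_id, "species": m.species, "family": m.family} for m in members
    ]
    return Catalog(params, families, members), ledger


# ---------------------------------------------------------------------------
# Stage 2: read counts


def generate_counts(catalog: Catalog, params: SimulationParams) -> pd.DataFrame:
    """Draw a locus x species count matrix.

    Counts are log2-normal (``round(2**N(mu, sd))``, floored at 1 so that a
    planted locus is always observed when ``dropout_prob`` is 0) with the
    conserved-family mean above the group-specific mean; a locus only has
    counts in its own species, and dropout silently zeroes a present locus
    with probability ``dropout_prob``.
    """
    rng = _stage_rng(params.seed, "counts")
    label = {f.name: f.label for f in catalog.families}
    species = params.all_species
    mat = pd.DataFrame(
        0, index=[m.locus_id for m in catalog.members], columns=species, dtype=np.int64
    )
    for m in catalog.members:
        mu = (
            params.expr_logmean_conserved
            if label[m.family] == "conserved"
            else params.expr_logmean_specific
        )
        if params.dropout_prob > 0 and rng.random() < params.dropout_prob:
            continue
        count = max(1, int(round(2.0 ** rng.normal(mu, params.expr_logsd))))
        mat.loc[m.locus_id, m.species] = count
    return mat


# ---------------------------------------------------------------------------
# Stage 3: genes, 3'UTRs, planted target sites, TPM


@dataclass
class GeneSet:
    transcripts: dict                  # species -> gene -> (sequence, stop_offset)
    tpm: pd.DataFrame                  # reference gene x species
    ortholog_map: pd.DataFrame         # species, species_gene, ref_gene, confidence


def _gene_roles(params: SimulationParams) -> dict[str, str]:
    roles = {g: "kernel" for g in params.kernel_genes}
    n = params.n_genes
    n_adj, n_out, n_dec = max(1, int(0.4 * n)), max(1, int(0.1 * n)), max(1, int(0.1 * n))
    for i in range(n):
        gid = f"G{i + 1:04d}"
        if i < n_adj:
            roles[gid] = "adjacent"
        elif i < n_adj + n_out:
            roles[gid] = "outsider"
        elif i < n_adj + n_out + n_dec:
            roles[gid] = "low_tpm_decoy"
        else:
            roles[gid] = "background"
    return roles


def _scrub(seq: list[str], lo: int, hi: int, forbidden: set[str], protected: list[tuple[int, int]],
           rng: np.random.Generator, kmin: int = 6, kmax: int = 7) -> None:
    """Mutate bases so no forbidden k-mer occurs in seq[lo:hi].

    Positions inside ``protected`` spans are never touched; an occurrence
    lying entirely within a protected span is left alone (planted content is
    hexamer-free by construction, so this only skips span-internal seed cores,
    which are intentional).
    """

    def in_protected(p: int) -> bool:
        return any(a <= p < b for a, b in protected)

    for _ in range(20):
        dirty = False
        for p in range(lo, hi - kmin + 1):
            for k in (kmin, kmax):
                if p + k > hi:
                    continue
                word = "".join(seq[p:p + k])
                if word in forbidden:
                    editable = [q for q in range(p, p + k) if not in_protected(q)]
                    if not editable:
                        continue
                    q = editable[int(rng.integers(0, len(editable)))]
                    others = [b for b in "ACGU" if b != seq[q]]
                    seq[q] = others[int(rng.integers(0, 3))]
                    dirty = True
        if not dirty:
            return
    raise RuntimeError("could not scrub forbidden k-mers")  # pragma: no cover


def generate_genes_and_utrs(
    catalog: Catalog, params: SimulationParams, ledger: GroundTruthLedger
) -> GeneSet:
    """Build per-species transcripts with planted 3'UTR target sites.

    Each transcript is a CDS ending in a UAA stop codon followed by a
    downstream region that contains the planted sites, exactly one AAUAAA
    hexamer at a drawn offset (the planted UTR ends at the final signal
    base), and a short tail.  Planted pair classes:

    ``grn``          full-support sites on kernel/kernel-adjacent genes —
                     expected to survive every downstream filter;
    ``low_support``  sites in a single species of one >=3-species group —
                     removed by the per-group conservation filter;
    ``low_tpm``      full-support sites on genes with TPM < 1 — removed by
                     the expression filter;
    ``non_kernel``   full-support sites on genes without kernel-adjacent
                     interactions — removed by the kernel filter.
    """
    rng = _stage_rng(params.seed, "genes")
    roles = _gene_roles(params)
    ledger.gene_roles = dict(roles)
    species = params.all_species
    species_by_group = params.species_by_group

    genes = list(roles)
    adjacent = [g for g in genes if roles[g] in ("kernel", "adjacent")]
    outsiders = [g for g in genes if roles[g] == "outsider"]
    decoys = [g for g in genes if roles[g] == "low_tpm_decoy"]

    fam_by_name = {f.name: f for f in catalog.families}
    pairs: list[dict] = []
    out_i = dec_i = 0
    for fam in catalog.families:
        n_take = min(params.sites_per_mirna, len(adjacent))
        take = rng.choice(len(adjacent), size=n_take, replace=False) if n_take else []
        for gi in take:
            pairs.append({"family": fam.name, "gene": adjacent[gi], "kind": "grn",
                          "species": list(fam.species)})
        if params.sites_per_mirna > 0:
            big_groups = [g for g, sp in species_by_group.items()
                          if len(sp) >= 3 and set(sp) <= set(fam.species)]
            if big_groups:
                g = big_groups[0]
                used = {p["gene"] for p in pairs if p["family"] == fam.name}
                cand = [x for x in adjacent if x not in used]
                if cand:
                    gi = int(rng.integers(0, len(cand)))
                    pairs.append({"family": fam.name, "gene": cand[gi], "kind": "low_support",
                                  "species": [species_by_group[g][0]]})
            if decoys:
                pairs.append({"family": fam.name, "gene": decoys[dec_i % len(decoys)],
                              "kind": "low_tpm", "species": list(fam.species)})
                dec_i += 1
            if outsiders:
                pairs.append({"family": fam.name, "gene": outsiders[out_i % len(outsiders)],
                              "kind": "non_kernel", "species": list(fam.species)})
                out_i += 1
    ledger.planted_pairs = pairs

    pairs_by_gene: dict[str, list[dict]] = {}
    for p in pairs:
        pairs_by_gene.setdefault(p["gene"], []).append(p)

    forbidden = {"AAUAAA", "AUUAAA"} | {revcomp(f.mature[1:7]) for f in catalog.families}

    cds_len = 60  # incl. stop codon at offset 57
    lo_off, hi_off = params.utr_signal_offset_range
    transcripts: dict[str, dict[str, tuple[str, int]]] = {sp: {} for sp in species}
    ledger.sites = {sp: {} for sp in species}

    for gene in genes:
        gpairs = pairs_by_gene.get(gene, [])
        slots = {}
        cursor = 10
        for p in gpairs:
            L = len(fam_by_name[p["family"]].site_seq)
            slots[(p["family"])] = (cursor, cursor + L)
            cursor += L + 6
        required = cursor + 10
        if hi_off < required:
            raise ValueError(
                f"utr_signal_offset_range upper bound {hi_off} below planted site load "
                f"({required} nt) on gene {gene}"
            )
        sig_off = int(rng.integers(max(lo_off, required), hi_off + 1))
        total = sig_off + 6 + 30

        cds = list(_random_rna(rng, cds_len - 3)) + list("UAA")
        background = list(_random_rna(rng, total))
        _scrub(background, 0, total, forbidden, [], rng)
        background[sig_off:sig_off + 6] = list("AAUAAA")
        decoy_spans: list[tuple[int, int]] = []
        if params.include_decoy_auuaaa:
            first_slot = min((s for s, _ in slots.values()), default=sig_off)
            if first_slot > 8:
                background[2:8] = list("AUUAAA")
                decoy_spans.append((2, 8))

        for sp in species:
            ds = list(background)
            spans = list(decoy_spans)
            for p in gpairs:
                if sp in p["species"]:
                    a, b = slots[p["family"]]
                    ds[a:b] = list(fam_by_name[p["family"]].site_seq)
                    spans.append((a, b))
                    ledger.sites[sp].setdefault(gene, []).append((p["family"], a, b))
            # planted sites may create signal hexamers at their junctions;
            # scrub those so the single planted AAUAAA defines the UTR
            _scrub(ds, 0, sig_off, {"AAUAAA", "AUUAAA"}, spans, rng)
            transcripts[sp][gene] = ("".join(cds) + "".join(ds), cds_len - 3)
        ledger.utr_boundaries[gene] = [0, sig_off + 6]

    tpm = pd.DataFrame(index=genes, columns=species, dtype=float)
    for sp in species:
        for gene in genes:
            if roles[gene] == "low_tpm_decoy":
                tpm.loc[gene, sp] = round(float(rng.uniform(0.0, 0.99)), 3)
            else:
                tpm.loc[gene, sp] = round(max(1.0, float(2.0 ** rng.normal(4.0, 1.5))), 3)

    rows = [
        {"species": sp, "species_gene": f"{gene}.{sp}", "ref_gene": gene, "confidence": "1"}
        for sp in species
        for gene in genes
    ]
    omap = pd.DataFrame(rows)
    return GeneSet(transcripts, tpm, omap)


# ---------------------------------------------------------------------------
# Stage 4: scored interaction table


def generate_ppi(params: SimulationParams, ledger: GroundTruthLedger) -> pd.DataFrame:
    """Emit a STRING-like scored edge table in three strata.

    (a) passing edges (experimental > 0, combined > experimental) between
    kernel genes and kernel-adjacent genes — every adjacent-role gene gets at
    least one; (b) edges failing the score rule; (c) passing edges confined
    to the outsider pool, disconnected from the kernel.
    """
    if not params.kernel_genes:
        raise ValueError("kernel_genes must be nonempty")
    rng = _stage_rng(params.seed, "ppi")
    roles = ledger.gene_roles or _gene_roles(params)
    kernel = [g for g, r in roles.items() if r == "kernel"]
    adjacent = [g for g, r in roles.items() if r == "adjacent"]
    outsiders = [g for g, r in roles.items() if r == "outsider"]
    non_decoy = [g for g, r in roles.items() if r != "low_tpm_decoy"]

    n_a = max(len(adjacent), int(0.6 * params.ppi_n_edges))
    n_b = max(1, int(0.2 * params.ppi_n_edges))
    n_c = max(1, params.ppi_n_edges - n_a - n_b)

    seen: set[tuple[str, str]] = set()
    rows: list[dict] = []

    def canon(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    def passing_scores() -> tuple[int, int]:
        exp = int(rng.integers(1, 701))
        return exp, int(rng.integers(exp + 1, 1001))

    def add(a: str, b: str, exp: int, comb: int, stratum: str) -> bool:
        e = canon(a, b)
        if a == b or e in seen:
            return False
        seen.add(e)
        rows.append({"gene_a": e[0], "gene_b": e[1], "experimental": exp,
                     "combined": comb, "stratum": stratum})
        return True

    for g in adjacent:  # guarantee kernel adjacency for every adjacent-role gene
        exp, comb = passing_scores()
        add(g, kernel[int(rng.integers(0, len(kernel)))], exp, comb, "a")
    n_have = sum(r["stratum"] == "a" for r in rows)
    attempts = 0
    while n_have < n_a and attempts < 50 * n_a:
        attempts += 1
        a = kernel[int(rng.integers(0, len(kernel)))]
        pool = kernel + adjacent
        b = pool[int(rng.integers(0, len(pool)))]
        exp, comb = passing_scores()
        n_have += add(a, b, exp, comb, "a")

    made = 0
    attempts = 0
    while made < n_b and attempts < 50 * n_b:
        attempts += 1
        a = non_decoy[int(rng.integers(0, len(non_decoy)))]
        b = non_decoy[int(rng.integers(0, len(non_decoy)))]
        if rng.random() < 0.5:
            exp, comb = 0, int(rng.integers(1, 1001))
        else:
            exp = int(rng.integers(1, 1001))
            comb = int(rng.integers(0, exp + 1))  # combined <= experimental
        made += add(a, b, exp, comb, "b")

    made = 0
    attempts = 0
    while made < n_c and len(outsiders) >= 2 and attempts < 50 * n_c:
        attempts += 1
        i, j = rng.choice(len(outsiders), size=2, replace=False)
        exp, comb = passing_scores()
        made += add(outsiders[i], outsiders[j], exp, comb, "c")

    ledger.ppi_strata = [dict(r) for r in rows]
    _record_planted_grn(params, ledger)
    return pd.DataFrame(rows)[["gene_a", "gene_b", "experimental", "combined"]]


def _record_planted_grn(params: SimulationParams, ledger: GroundTruthLedger) -> None:
    """Derive, by construction, the per-group edge set expected downstream."""
    ppi_a = sorted(
        (r["gene_a"], r["gene_b"]) for r in ledger.ppi_strata if r["stratum"] == "a"
    )
    ledger.planted_grn = {}
    for group, sp in ledger.groups.items():
        mir_edges = set()
        for p in ledger.planted_pairs:
            if p["kind"] != "grn":
                continue
            label = ledger.labels[p["family"]]
            if label == "conserved" or label == f"group_specific:{group}":
                mir_edges.add((p["family"], p["gene"]))
        ledger.planted_grn[group] = {
            "ppi": [list(e) for e in ppi_a],
            "mir_target": sorted([list(e) for e in mir_edges]),
        }


# ---------------------------------------------------------------------------
# Orchestration + file output


def simulate(params: SimulationParams):
    """Run all generator stages; returns (catalog, counts, genes, ppi, ledger)."""
    catalog, ledger = generate_catalog(params)
    counts = generate_counts(catalog, params)
    geneset = generate_genes_and_utrs(catalog, params, ledger)
    ppi = generate_ppi(params, ledger)
    return catalog, counts, geneset, ppi, ledger


def write_inputs(params: SimulationParams, outdir: str | Path) -> GroundTruthLedger:
    """Generate everything and write the pipeline's input files to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog, counts, geneset, ppi, ledger = simulate(params)

    by_species: dict[str, list[Member]] = {sp: [] for sp in params.all_species}
    for m in catalog.members:
        by_species[m.species].append(m)
    for sp, members in by_species.items():
        io.write_fasta(
            outdir / f"precursors_{sp}.fasta",
            [io.FastaRecord(m.locus_id, m.precursor, {"species": sp, "arm": m.arm})
             for m in members],
        )
        io.write_fasta(
            outdir / f"matures_{sp}.fasta",
            [io.FastaRecord(m.locus_id, m.mature, {"species": sp, "arm": m.arm})
             for m in members],
        )

    ref = [
        io.FastaRecord(f"{f.name}|ref", f.precursor, {"family": f.name, "tier": "primary"})
        for f in catalog.families
    ]
    io.write_fasta(outdir / "reference_primary.fasta", ref)
    if params.emit_secondary_reference:
        io.write_fasta(
            outdir / "reference_secondary.fasta",
            [io.FastaRecord(r.id, r.seq, {**r.attrs, "tier": "secondary"}) for r in ref],
        )

    io.write_matrix_tsv(counts, outdir / "counts.tsv")
    ages = pd.DataFrame(
        {"family": list(ledger.family_age), "age_mya": list(ledger.family_age.values())}
    )
    io.write_tsv(ages, outdir / "ages.tsv")

    for sp in params.all_species:
        recs = [
            io.FastaRecord(f"{gene}.{sp}", seq,
                           {"stop_offset": str(stop), "gene": gene, "species": sp})
            for gene, (seq, stop) in geneset.transcripts[sp].items()
        ]
        io.write_fasta(outdir / f"transcripts_{sp}.fasta", recs)
        tpm_sp = pd.DataFrame({
            "species_gene": [f"{g}.{sp}" for g in geneset.tpm.index],
            "tpm": geneset.tpm[sp].to_numpy(),
        })
        io.write_tsv(tpm_sp, outdir / f"tpm_{sp}.tsv")

    io.write_tsv(geneset.ortholog_map, outdir / "orthologs.tsv")
    io.write_tsv(ppi, outdir / "ppi.tsv")
    io.write_tsv(pd.DataFrame({"gene": list(params.kernel_genes)}), outdir / "kernel.tsv")

    validated = [
        {"mirna_family": p["family"], "gene": p["gene"], "source": "synthetic-db"}
        for p in ledger.planted_pairs[:5] if p["kind"] == "grn"
    ]
    io.write_tsv(pd.DataFrame(validated, columns=["mirna_family", "gene", "source"]),
                 outdir / "validated.tsv")

    groups_tbl = pd.DataFrame(
        [(sp, g) for g, spl in ledger.groups.items() for sp in spl],
        columns=["species", "group"],
    )
    io.write_tsv(groups_tbl, outdir / "groups.tsv")
    io.write_json(ledger.to_json(), outdir / "ledger.json")
    return ledger
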