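"""Synthetic protein families and hit tables with planted ground truth.

Every stage of the signature-discovery pipeline is testable without any
database download: families of aligned homologs are generated over a
labelled clade tree with clade-specific indels planted between conserved
flanks (plus decoy families that must *not* be called), and homology hit
tables are generated with planted clade-restricted proteins whose
in-group E-values are tiny and whose out-group hits are absent or weak.

Sequences evolve star-wise: each genome's sequence is mutated
independently from a common root at a per-site substitution probability,
with the columns flanking a planted indel protected at a (default zero)
reduced rate so the flank-conservation filter has signal to find.  The
generator is fully deterministic under its seed and records exact truth
(block columns, per-genome indel lengths, planted clade) for every unit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

from .alignments import AMINO_ACIDS, GAP, Alignment, SequenceRecord, \
    write_alignment
from .csp import HomologyHit
from .taxonomy import CladeTree, build_clade_tree, write_taxonomy

_AA = np.array(list(AMINO_ACIDS))

DECOY_MODES = ("none", "nonspecific_indel", "weak_flank", "partial_clade")


@dataclass(frozen=True)
class PlantedIndel:
    clade: str
    indel_type: str  # "insertion" | "deletion"
    len_min: int
    len_max: int

    def __post_init__(self) -> None:
        if self.indel_type not in ("insertion", "deletion"):
            raise ValueError(f"bad indel_type {self.indel_type!r}")
        if not 1 <= self.len_min <= self.len_max:
            raise ValueError("need 1 <= len_min <= len_max")


@dataclass
class FamilyParams:
    """Parameters of one simulated protein family.

    ``sub_prob`` is the per-site, per-genome substitution probability
    away from the root sequence; ``flank_protect`` columns on each side
    of a planted indel mutate at ``protected_sub_prob`` instead (default
    0: perfectly conserved flanks).  ``decoy_mode`` generates families
    that carry no clade-specific signal and must yield zero calls:
    ``nonspecific_indel`` leaks the indel into one out-group genome,
    ``weak_flank`` mutates the flanks at ``weak_flank_sub_prob``,
    ``partial_clade`` plants the indel in only half the clade.
    """

    seed: int
    tree: CladeTree
    seq_len: int = 400
    sub_prob: float = 0.05
    flank_protect: int = 40
    protected_sub_prob: float = 0.0
    weak_flank_sub_prob: float = 0.5
    planted: Optional[PlantedIndel] = None
    decoy_mode: str = "none"
    family_id: str = "fam0000"

    def __post_init__(self) -> None:
        if self.decoy_mode not in DECOY_MODES:
            raise ValueError(f"unknown decoy_mode {self.decoy_mode!r}")
        if not 0 <= self.sub_prob <= 1:
            raise ValueError("sub_prob must lie in [0, 1]")
        if self.planted is not None:
            if self.planted.clade not in self.tree:
                raise ValueError(
                    f"planted clade {self.planted.clade!r} unknown to tree")
            need = 2 * self.flank_protect + self.planted.len_max + 2
            if self.seq_len < need:
                raise ValueError(
                    f"seq_len {self.seq_len} too short for flank_protect "
                    f"{self.flank_protect} plus indel")


@dataclass
class FamilyTruth:
    """Exact ground truth for one generated family."""

    family_id: str
    is_signature: bool
    clade: Optional[str]
    indel_type: Optional[str]
    col_start: Optional[int]  # 1-based block columns in the alignment
    col_end: Optional[int]
    size_min: Optional[int]
    size_max: Optional[int]
    carriers: tuple[str, ...]
    decoy_mode: str
    locus: Optional[int]  # root residue position after which the indel sits


def _mutate(rng: np.random.Generator, seq: np.ndarray,
            prob: np.ndarray) -> np.ndarray:
    """Substitute each site with its own probability, never back to the
    original residue."""
    out = seq.copy()
    mask = rng.random(len(seq)) < prob
    if mask.any():
        # offset 1..19 from the current residue index, modulo 20
        idx = np.searchsorted(_AA, out[mask])
        offset = rng.integers(1, 20, size=mask.sum())
        out[mask] = _AA[(idx + offset) % 20]
    return out


def simulate_family(params: FamilyParams) -> tuple[Alignment, FamilyTruth]:
    """Generate one aligned family, with exact planted truth.

    The root sequence is uniform over the 20 amino acids.  If an indel is
    planted, a locus is drawn once (far enough from the termini to leave
    full protected flanks), and every genome of the planted clade either
    gains residues there (insertion: per-carrier length drawn in
    ``[len_min, len_max]``, left-aligned in a block padded to the longest
    carrier) or loses a fixed-length segment (deletion: single length for
    all carriers).  The alignment is produced by construction — gap
    columns are placed exactly where the indel is — so the truth block
    columns are exact.  Identical seeds give identical output.
    """
    rng = np.random.default_rng(params.seed)
    genomes = sorted(params.tree.memberships)
    root = _AA[rng.integers(0, 20, size=params.seq_len)]

    planted = params.planted
    if params.decoy_mode != "none" and planted is None:
        raise ValueError(f"decoy_mode {params.decoy_mode!r} needs a planted indel")

    locus: Optional[int] = None
    lengths: dict[str, int] = {}
    carriers: list[str] = []
    indel_type = None
    if planted is not None:
        indel_type = planted.indel_type
        clade_genomes = sorted(params.tree.genomes_under(planted.clade))
        carriers = list(clade_genomes)
        uniform_len = params.decoy_mode == "nonspecific_indel" or \
            indel_type == "deletion"
        if params.decoy_mode == "partial_clade":
            carriers = carriers[:max(1, len(carriers) // 2)]
        lo = params.flank_protect
        hi = params.seq_len - params.flank_protect - \
            (planted.len_max if indel_type == "deletion" else 0)
        locus = int(rng.integers(lo, hi + 1))
        if uniform_len:
            shared = int(rng.integers(planted.len_min, planted.len_max + 1))
            lengths = {g: shared for g in carriers}
        else:
            lengths = {g: int(rng.integers(planted.len_min,
                                           planted.len_max + 1))
                       for g in carriers}
        if params.decoy_mode == "nonspecific_indel":
            outsiders = [g for g in genomes if g not in clade_genomes]
            leak = outsiders[int(rng.integers(0, len(outsiders)))]
            carriers.append(leak)
            lengths[leak] = next(iter(lengths.values())) if lengths else 1

    # per-column substitution probability (root coordinates)
    prob = np.full(params.seq_len, params.sub_prob)
    if planted is not None and locus is not None:
        flank_rate = (params.weak_flank_sub_prob
                      if params.decoy_mode == "weak_flank"
                      else params.protected_sub_prob)
        if indel_type == "insertion":
            left = range(max(0, locus - params.flank_protect), locus)
            right = range(locus, min(params.seq_len,
                                     locus + params.flank_protect))
        else:
            dlen = next(iter(lengths.values()))
            left = range(max(0, locus - params.flank_protect), locus)
            right = range(locus + dlen,
                          min(params.seq_len,
                              locus + dlen + params.flank_protect))
        prob[list(left)] = flank_rate
        prob[list(right)] = flank_rate

    width = max(lengths.values()) if (planted is not None
                                      and indel_type == "insertion") else 0
    records = []
    for genome in genomes:
        seq = _mutate(rng, root, prob)
        text = "".join(seq)
        if planted is None or locus is None:
            residues = text
        elif indel_type == "insertion":
            if genome in lengths:
                n = lengths[genome]
                ins = "".join(_AA[rng.integers(0, 20, size=n)])
                block = ins + GAP * (width - n)
            else:
                block = GAP * width
            residues = text[:locus] + block + text[locus:]
        else:  # deletion
            dlen = next(iter(lengths.values()))
            if genome in lengths:
                residues = text[:locus] + GAP * dlen + text[locus + dlen:]
            else:
                residues = text
        records.append(SequenceRecord(f"{params.family_id}_{genome}",
                                      genome, residues))
    alignment = Alignment(records, name=params.family_id)

    if planted is None or locus is None:
        truth = FamilyTruth(params.family_id, False, None, None, None, None,
                            None, None, (), params.decoy_mode, None)
    else:
        if indel_type == "insertion":
            col_start, col_end = locus + 1, locus + width
        else:
            dlen = next(iter(lengths.values()))
            col_start, col_end = locus + 1, locus + dlen
        sizes = [lengths[g] for g in carriers]
        truth = FamilyTruth(
            params.family_id,
            is_signature=(params.decoy_mode == "none"),
            clade=planted.clade, indel_type=indel_type,
            col_start=col_start, col_end=col_end,
            size_min=min(sizes), size_max=max(sizes),
            carriers=tuple(carriers), decoy_mode=params.decoy_mode,
            locus=locus)
    return alignment, truth


# ---------------------------------------------------------------------------
# hit tables


@dataclass
class HitTableParams:
    """Parameters of a simulated homology-search result set.

    Planted clade-restricted queries get one strong hit per in-group
    genome (log10 E uniform in ``ingroup_e_log10_range``) and, per
    out-group genome, either no hit (probability ``outgroup_absent_prob``)
    or a weak one (E uniform in ``outgroup_e_range``, above the exclusion
    threshold).  ``contamination`` decoys look planted but carry one
    out-group hit below the significance threshold; the remaining decoys
    are cosmopolitan proteins with strong hits everywhere.
    """

    seed: int
    tree: CladeTree
    ingroup: str
    n_queries: int = 500
    frac_planted_csp: float = 0.5
    ingroup_e_log10_range: tuple[float, float] = (-80.0, -20.0)
    outgroup_absent_prob: float = 0.7
    outgroup_e_range: tuple[float, float] = (1.0, 10.0)
    contamination: int = 0
    contaminant_e_range: tuple[float, float] = (1e-4, 9e-3)

    def __post_init__(self) -> None:
        if not 0 <= self.frac_planted_csp <= 1:
            raise ValueError("frac_planted_csp must lie in [0, 1]")
        if not 0 <= self.outgroup_absent_prob <= 1:
            raise ValueError("outgroup_absent_prob must lie in [0, 1]")
        for lo, hi in (self.ingroup_e_log10_range, self.outgroup_e_range,
                       self.contaminant_e_range):
            if lo > hi:
                raise ValueError("E-value ranges must be ordered")
        n_planted = round(self.n_queries * self.frac_planted_csp)
        if self.contamination > self.n_queries - n_planted:
            raise ValueError("contamination exceeds the number of decoys")


@dataclass
class QueryTruth:
    query_id: str
    is_csp: bool
    clade: Optional[str]
    contaminated: bool
    presence: tuple[str, ...]


def simulate_hit_tables(params: HitTableParams
                        ) -> tuple[dict[str, list[HomologyHit]],
                                   list[QueryTruth]]:
    """Generate per-query hit lists and their truth labels."""
    rng = np.random.default_rng(params.seed)
    in_genomes = sorted(params.tree.genomes_under(params.ingroup))
    out_genomes = sorted(params.tree.genomes - set(in_genomes))
    n_planted = round(params.n_queries * params.frac_planted_csp)

    hits: dict[str, list[HomologyHit]] = {}
    truth: list[QueryTruth] = []
    for i in range(params.n_queries):
        query = f"q{i + 1:04d}"
        is_planted = i < n_planted
        contaminated = (not is_planted
                        and i < n_planted + params.contamination)
        rows: list[HomologyHit] = []
        if is_planted or contaminated:
            lo, hi = params.ingroup_e_log10_range
            for g in in_genomes:
                e = float(10.0 ** rng.uniform(lo, hi))
                rows.append(HomologyHit(query, f"{g}_h{i}", g, e,
                                        bit_score=float(rng.uniform(200, 900))))
            for g in out_genomes:
                if rng.random() >= params.outgroup_absent_prob:
                    e = float(rng.uniform(*params.outgroup_e_range))
                    rows.append(HomologyHit(query, f"{g}_h{i}", g, e,
                                            bit_score=float(rng.uniform(15, 35))))
            if contaminated:
                g = out_genomes[int(rng.integers(0, len(out_genomes)))]
                e = float(rng.uniform(*params.contaminant_e_range))
                rows.append(HomologyHit(query, f"{g}_x{i}", g, e,
                                        bit_score=float(rng.uniform(40, 80))))
        else:  # cosmopolitan decoy: strong hits inside and outside
            for g in in_genomes + out_genomes:
                e = float(10.0 ** rng.uniform(-60, -10))
                rows.append(HomologyHit(query, f"{g}_h{i}", g, e,
                                        bit_score=float(rng.uniform(100, 600))))
        hits[query] = rows
        truth.append(QueryTruth(
            query_id=query, is_csp=is_planted,
            clade=params.ingroup if is_planted else None,
            contaminated=contaminated,
            presence=tuple(in_genomes) if (is_planted or contaminated) else ()))
    return hits, truth


def write_hit_table(hits: dict[str, list[HomologyHit]], path) -> None:
    """Write hits as 13-column tabular rows (outfmt-6 plus genome)."""
    with open(path, "w") as fh:
        for query in hits:
            for h in hits[query]:
                bit = h.bit_score if h.bit_score is not None else 0.0
                fh.write("\t".join([
                    h.query_id, h.subject_id, "50.0", "100", "50", "0",
                    "1", "100", "1", "100", f"{h.e_value:.6g}",
                    f"{bit:.1f}", h.subject_genome]) + "\n")


# ---------------------------------------------------------------------------
# benchmark bundles


def default_benchmark_tree(n_ingroup: int = 12,
                           n_outgroup: int = 12) -> CladeTree:
    """A two-order taxonomy: target clade ``CladeA`` (two families of
    in-group genomes ``A01..``) and comparison clade ``CladeB``."""
    rows = []
    half = (n_ingroup + 1) // 2
    for i in range(n_ingroup):
        family = "FamA1" if i < half else "FamA2"
        rows.append((f"A{i + 1:02d}", ["Bacteria", "CladeA", family]))
    half_b = (n_outgroup + 1) // 2
    for i in range(n_outgroup):
        family = "FamB1" if i < half_b else "FamB2"
        rows.append((f"B{i + 1:02d}", ["Bacteria", "CladeB", family]))
    return build_clade_tree(rows)


def benchmark_families(n_families: int, seed: int, tree: CladeTree,
                       clade: str = "CladeA", kind: str = "signature",
                       seq_len: int = 400, sub_prob: float = 0.05,
                       flank_protect: int = 40,
                       len_min: int = 1, len_max: int = 8
                       ) -> Iterator[tuple[Alignment, FamilyTruth]]:
    """Stream benchmark families: planted signatures or decoys.

    Signature families alternate insertion / deletion.  Decoy families
    cycle through the three decoy modes (non-specific indel, weak flanks,
    partial-clade carriers).  Family ``i`` uses seed ``seed + i`` so any
    family regenerates independently.
    """
    if kind not in ("signature", "decoy"):
        raise ValueError(f"unknown benchmark kind {kind!r}")
    decoys = ("nonspecific_indel", "weak_flank", "partial_clade")
    for i in range(n_families):
        indel_type = "insertion" if i % 2 == 0 else "deletion"
        params = FamilyParams(
            seed=seed + i, tree=tree, seq_len=seq_len, sub_prob=sub_prob,
            flank_protect=flank_protect,
            planted=PlantedIndel(clade, indel_type, len_min, len_max),
            decoy_mode="none" if kind == "signature" else decoys[i % 3],
            family_id=f"{kind[:3]}{i:04d}")
        yield simulate_family(params)


def simulate_benchmark(out_dir, n_families: int = 200, seed: int = 1,
                       hit_params: Optional[HitTableParams] = None,
                       n_decoys: int = 0,
                       tree: Optional[CladeTree] = None) -> dict:
    """Write a full benchmark bundle to disk and return its manifest.

    Layout: ``alignments/<family>.fasta``, ``taxonomy.tsv``, ``hits.tsv``,
    ``truth_families.tsv``, ``truth_queries.tsv`` and ``manifest.json``
    (parameter echo plus per-file SHA-256 checksums).  Re-running with the
    same parameters reproduces identical bytes.
    """
    out = Path(out_dir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    tree = tree or default_benchmark_tree()
    write_taxonomy(tree, out / "taxonomy.tsv")

    fam_rows = []
    for kind, n, offset in (("signature", n_families, 0),
                            ("decoy", n_decoys, n_families)):
        for aln, truth in benchmark_families(n, seed + offset, tree,
                                             kind=kind):
            write_alignment(aln, out / "alignments" / f"{truth.family_id}.fasta")
            fam_rows.append(truth)
    with open(out / "truth_families.tsv", "w") as fh:
        fh.write("family_id\tis_signature\tclade\tindel_type\tcol_start\t"
                 "col_end\tsize_min\tsize_max\tdecoy_mode\tcarriers\n")
        for t in fam_rows:
            fh.write("\t".join(str(x) if x is not None else "" for x in (
                t.family_id, int(t.is_signature), t.clade, t.indel_type,
                t.col_start, t.col_end, t.size_min, t.size_max,
                t.decoy_mode, ",".join(t.carriers))) + "\n")

    if hit_params is not None:
        hits, q_truth = simulate_hit_tables(hit_params)
        write_hit_table(hits, out / "hits.tsv")
        with open(out / "truth_queries.tsv", "w") as fh:
            fh.write("query_id\tis_csp\tclade\tcontaminated\tpresence\n")
            for t in q_truth:
                fh.write("\t".join([t.query_id, str(int(t.is_csp)),
                                    t.clade or "", str(int(t.contaminated)),
                                    ",".join(t.presence)]) + "\n")

    manifest = {
        "seed": seed, "n_families": n_families, "n_decoys": n_decoys,
        "hit_params": None if hit_params is None else {
            "seed": hit_params.seed, "ingroup": hit_params.ingroup,
            "n_queries": hit_params.n_queries,
            "frac_planted_csp": hit_params.frac_planted_csp,
            "contamination": hit_params.contamination},
        "checksums": {},
    }
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest["checksums"][str(path.relative_to(out))] = digest
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
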