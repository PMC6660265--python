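"""Synthetic genomes with planted motif architectures and exact truth.

Background sequence is rejection-sampled so that, inside every promoter
window, no RCGTG and no HAS 5-mer exists outside the planted sites and
no planted HRE is accidentally preceded by a C (which would turn it
into an E-box). Ground truth is therefore exact, not probabilistic: a
scan of the generated windows must recover the manifest with zero false
positives and zero false negatives.

All randomness flows from a single integer seed; the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field

from .annotation_io import GeneRecord
from .motif_scan import HAS_5MERS, HRE_5MERS, MOTIF_LEN, RegionScheme
from .promoter_extract import WindowSpec, axis_index, rel_to_genomic, revcomp

_FORBIDDEN = frozenset(HRE_5MERS) | frozenset(HAS_5MERS)

# E-box plants use the C+GCGTG context form: the canonical CACGTG embeds
# a HAS 5-mer (CACGT) entirely within the planted bases, which would
# break the exact-truth guarantee.
_EBOX_CORE = "GCGTG"


@dataclass(frozen=True)
class PlantSpec:
    """One motif to plant in a gene's promoter window.

    ``rel_pos`` is the relative position of the motif's 5' base (for
    E-box, of the RCGTG core; the C context base sits one position 5').
    ``gap`` applies to kind ``HRE_HAS`` only.
    """

    gene_id: str
    chrom: str
    strand: str
    kind: str  # HRE | HRE_HAS | EBOX | HAS
    rel_pos: int
    gap: int = 9

    def __post_init__(self) -> None:
        if self.kind not in {"HRE", "HRE_HAS", "EBOX", "HAS"}:
            raise ValueError(f"unknown plant kind {self.kind!r}")
        if self.kind == "HRE_HAS" and self.gap < 0:
            raise ValueError("gap must be >= 0")


@dataclass
class SyntheticDataset:
    sequences: dict[str, str]
    genes: list[GeneRecord]
    manifest: list[dict]
    seed: int
    window: WindowSpec

    def write(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "genome.fa"), "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(os.path.join(outdir, "genes.tsv"), "w") as fh:
            fh.write("gene_id\tsymbol\tchrom\tstrand\tstart\tend\n")
            for g in self.genes:
                fh.write(f"{g.gene_id}\t{g.symbol}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\n")
        with open(os.path.join(outdir, "manifest.jsonl"), "w") as fh:
            fh.write(json.dumps({"seed": self.seed,
                                 "window": [self.window.rel_start, self.window.rel_end]}) + "\n")
            for entry in self.manifest:
                fh.write(json.dumps(entry) + "\n")


def _offset(window: WindowSpec, r: int) -> int:
    return axis_index(r) - axis_index(window.rel_start)


def _rel_at(window: WindowSpec, off: int) -> int:
    idx = axis_index(window.rel_start) + off
    return idx if idx < 0 else idx + 1


def _sample_base(rng: random.Random, gc_frac: float) -> str:
    return rng.choices("ACGT", weights=[(1 - gc_frac) / 2, gc_frac / 2, gc_frac / 2, (1 - gc_frac) / 2])[0]


def _build_window(
    rng: random.Random,
    window: WindowSpec,
    plants: list[PlantSpec],
    gc_frac: float,
) -> tuple[list[str], list[dict]]:
    """Window char array with plants placed and clean background."""
    L = window.length
    arr: list[str | None] = [None] * L
    fixed = [False] * L
    spans: set[tuple[int, int]] = set()  # expected motif-hit spans
    hre_starts: list[int] = []  # plain-HRE offsets needing a non-C context
    entries: list[dict] = []

    def place(off: int, mer: str, spec: PlantSpec) -> None:
        if off < 0 or off + len(mer) > L:
            raise ValueError(f"plant {spec} does not fit the window")
        for j, ch in enumerate(mer):
            if fixed[off + j]:
                raise ValueError(f"plant {spec} overlaps another planted motif")
            arr[off + j] = ch
            fixed[off + j] = True

    for spec in plants:
        o = _offset(window, spec.rel_pos)
        if spec.kind in {"HRE", "HRE_HAS"}:
            mer = rng.choice(sorted(HRE_5MERS))
            place(o, mer, spec)
            spans.add((o, o + MOTIF_LEN - 1))
            if o > 0:
                hre_starts.append(o)
            entries.append({"kind": "HRE", "off": o, "seq": mer})
            if spec.kind == "HRE_HAS":
                ho = o + MOTIF_LEN + spec.gap
                hmer = rng.choice(sorted(HAS_5MERS))
                place(ho, hmer, spec)
                spans.add((ho, ho + MOTIF_LEN - 1))
                entries.append({"kind": "HAS", "off": ho, "seq": hmer})
        elif spec.kind == "EBOX":
            if o < 1:
                raise ValueError(f"E-box plant {spec} needs a context base inside the window")
            place(o - 1, "C" + _EBOX_CORE, spec)
            spans.add((o, o + MOTIF_LEN - 1))
            entries.append({"kind": "EBOX", "off": o, "seq": _EBOX_CORE,
                            "context": "C" + _EBOX_CORE})
        else:  # free-standing HAS
            hmer = rng.choice(sorted(HAS_5MERS))
            place(o, hmer, spec)
            spans.add((o, o + MOTIF_LEN - 1))
            entries.append({"kind": "HAS", "off": o, "seq": hmer})

    for i in range(L):
        if arr[i] is None:
            arr[i] = _sample_base(rng, gc_frac)

    # repair: resample background bases until no unplanned motif exists
    for _round in range(500):
        dirty: set[int] = set()
        for i in range(L - MOTIF_LEN + 1):
            if (i, i + MOTIF_LEN - 1) in spans:
                continue
            if "".join(arr[i : i + MOTIF_LEN]) in _FORBIDDEN:
                bg = [j for j in range(i, i + MOTIF_LEN) if not fixed[j]]
                if not bg:
                    raise AssertionError("unplanned motif made of planted bases only")
                dirty.add(rng.choice(bg))
        for o in hre_starts:
            if arr[o - 1] == "C":
                if fixed[o - 1]:
                    raise AssertionError("planted base forces E-box context on an HRE plant")
                dirty.add(o - 1)
        if not dirty:
            break
        for j in dirty:
            arr[j] = _sample_base(rng, gc_frac)
    else:
        raise AssertionError("background repair did not converge")
    return arr, entries  # type: ignore[return-value]


def make_genome(
    plants: list[PlantSpec],
    chrom_lengths: dict[str, int],
    gc_frac: float = 0.41,
    seed: int = 0,
    window: WindowSpec = WindowSpec(),
    scheme: RegionScheme = RegionScheme(),
    margin: int = 20,
) -> SyntheticDataset:
    """Assemble chromosomes with one promoter window per planted gene.

    Genes are laid left to right along each chromosome with ``margin``
    nt between windows; the manifest records every planted motif with
    relative and genomic coordinates, region label and, for HRE+HAS
    plants, the linking gap.
    """
    rng = random.Random(seed)

    by_gene: dict[str, list[PlantSpec]] = {}
    for spec in plants:
        by_gene.setdefault(spec.gene_id, []).append(spec)
    for gid, specs in by_gene.items():
        if len({(s.chrom, s.strand) for s in specs}) != 1:
            raise ValueError(f"gene {gid}: plants disagree on chromosome/strand")

    # independent per-chromosome background, genes in insertion order
    chrom_arrays = {
        name: [_sample_base(rng, gc_frac) for _ in range(length)]
        for name, length in chrom_lengths.items()
    }
    cursors = {name: 1 for name in chrom_lengths}
    genes: list[GeneRecord] = []
    manifest: list[dict] = []

    for gid, specs in by_gene.items():
        chrom, strand = specs[0].chrom, specs[0].strand
        if chrom not in chrom_arrays:
            raise ValueError(f"gene {gid}: unknown chromosome {chrom!r}")
        gmin = cursors[chrom]
        gmax = gmin + window.length - 1
        if gmax > chrom_lengths[chrom]:
            raise ValueError(f"chromosome {chrom} too short to place gene {gid}")
        cursors[chrom] = gmax + 1 + margin

        if strand == "+":
            start = gmin - window.rel_start  # rel_start < 0
            gene = GeneRecord(gid, gid, chrom, "+", start, start + 1)
        else:
            end = gmin + window.rel_end - 1
            gene = GeneRecord(gid, gid, chrom, "-", end - 1, end)
        genes.append(gene)

        arr, entries = _build_window(rng, window, specs, gc_frac)
        win_seq = "".join(arr)
        genomic = win_seq if strand == "+" else revcomp(win_seq)
        chrom_arrays[chrom][gmin - 1 : gmax] = list(genomic)

        hit_rows = []
        for e in entries:
            r5 = _rel_at(window, e["off"])
            r3 = _rel_at(window, e["off"] + MOTIF_LEN - 1)
            g5 = rel_to_genomic(gene, r5)
            g3 = rel_to_genomic(gene, r3)
            row = {
                "gene_id": gid,
                "chrom": chrom,
                "strand": strand,
                "kind": e["kind"],
                "rel_start": r5,
                "rel_end": r3,
                "genomic_start": min(g5, g3),
                "genomic_end": max(g5, g3),
                "matched_seq": e["seq"],
                "region": scheme.assign(r5),
            }
            if "context" in e:
                row["context_6mer"] = e["context"]
            hit_rows.append(row)
        manifest.extend(hit_rows)

        # pairs implied by the planted motifs under the default gap rule,
        # by brute-force double loop over this gene's planted hits
        hres = [r for r in hit_rows if r["kind"] == "HRE"]
        hass = [r for r in hit_rows if r["kind"] == "HAS"]
        for h in hres:
            for a in hass:
                gap = axis_index(a["rel_start"]) - axis_index(h["rel_end"]) - 1
                if 7 <= gap <= 15:
                    manifest.append({
                        "gene_id": gid, "kind": "PAIR",
                        "hre_rel_start": h["rel_start"],
                        "has_rel_start": a["rel_start"], "gap": gap,
                    })

    sequences = {name: "".join(a) for name, a in chrom_arrays.items()}
    return SyntheticDataset(sequences, genes, manifest, seed, window)


def default_fixture(
    seed: int = 0,
    n_genes: int = 80,
    window: WindowSpec = WindowSpec(),
) -> SyntheticDataset:
    """A mixed fixture: both strands, all plant kinds, all regions.

    Each gene carries 1-3 plants drawn over the whole window, giving
    a few hundred planted sites at the default size.
    """
    rng = random.Random(seed + 1)
    lo = axis_index(window.rel_start)
    hi = axis_index(window.rel_end)
    plants: list[PlantSpec] = []
    for i in range(n_genes):
        gid = f"g{i:04d}"
        chrom = f"chr{1 + i % 2}"
        strand = "+" if i % 2 == 0 else "-"
        used: list[tuple[int, int]] = []
        for _ in range(1 + rng.randrange(3)):
            kind = rng.choice(["HRE", "HRE", "HRE_HAS", "EBOX"])
            gap = rng.randrange(7, 16)
            need = MOTIF_LEN + (MOTIF_LEN + gap if kind == "HRE_HAS" else 0)
            for _try in range(50):
                idx = rng.randrange(lo + 2, hi - need - 1)
                span = (idx - 1, idx + need)  # 1-base cushion around plants
                if all(span[1] < a or span[0] > b for a, b in used):
                    used.append(span)
                    r = idx if idx < 0 else idx + 1
                    plants.append(PlantSpec(gid, chrom, strand, kind, r, gap))
                    break
    lengths = {
        c: (window.length + 21) * max(1, len({p.gene_id for p in plants if p.chrom == c})) + 100
        for c in ("chr1", "chr2")
    }
    return make_genome(plants, lengths, seed=seed, window=window)


@dataclass(frozen=True)
class MrnaPlan:
    """One query/subject mRNA pair with a target percent identity."""

    query_gene: str
    subject_gene: str
    target_identity_pct: float
    length: int = 300


def make_mrna_sets(
    plan: list[MrnaPlan], seed: int = 0
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], list[dict], dict[str, str], dict[str, str]]:
    """Generate mRNA pairs mutated to requested identities.

    Substitutions are kept away from the first/last 10 nt so a local
    alignment spans the full sequence and the measured identity lands
    within about two points of the target. Returns query records,
    subject records, a truth table, and mRNA->gene maps for both sides.
    """
    rng = random.Random(seed + 7)
    queries: list[tuple[str, str]] = []
    subjects: list[tuple[str, str]] = []
    truth: list[dict] = []
    qmap: dict[str, str] = {}
    smap: dict[str, str] = {}
    for entry in plan:
        if not 0 < entry.target_identity_pct <= 100:
            raise ValueError("target identity must be in (0, 100]")
        L = entry.length
        subject = "".join(rng.choice("ACGT") for _ in range(L))
        n_sub = round(L * (1 - entry.target_identity_pct / 100))
        if n_sub > max(0, L - 20):
            raise ValueError(f"{entry}: too many substitutions for length {L}")
        positions = rng.sample(range(10, L - 10), n_sub) if n_sub else []
        q = list(subject)
        for p in positions:
            q[p] = rng.choice([b for b in "ACGT" if b != q[p]])
        qid, sid = f"m_{entry.query_gene}", f"m_{entry.subject_gene}"
        queries.append((qid, "".join(q)))
        subjects.append((sid, subject))
        qmap[qid] = entry.query_gene
        smap[sid] = entry.subject_gene
        truth.append({
            "query_gene": entry.query_gene,
            "subject_gene": entry.subject_gene,
            "target_identity_pct": entry.target_identity_pct,
            "n_substitutions": n_sub,
            "exact_identity_pct": 100.0 * (L - n_sub) / L,
        })
    return queries, subjects, truth, qmap, smap


def write_fasta(records: list[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
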