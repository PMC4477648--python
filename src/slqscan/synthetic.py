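"""Synthetic genomes with planted ground truth for pipeline validation.

The generator emulates the features of genomic sequence that the scanner and
screen react to, under controlled conditions:

* planted SLQS: four G-tracts (lengths 3-6) separated by one to three long
  loops, each long loop carrying a designed complementary stem of >= 4
  canonical pairs around a >= 3-nt hairpin loop so that paired bases cover at
  least half of the extended loop;
* planted PQS_L7: four G-tracts with all loops <= 7 nt;
* decoys: (i) long-loop motifs whose loop content is complementarity-free,
  (ii) three-tract near-misses, (iii) C-strand motifs (reverse complements of
  SLQS, recoverable only on the minus strand);
* spacers: G-poor random sequence in which every G- or C-run of >= 3 nt has
  been broken, so planted motifs are the only tract sources and recovery is
  exact.

Every planted motif is verified at generation time by excising it with 10-nt
flanks and running the actual scanner + classifier; a motif that cannot be
built to satisfy its own contract raises :class:`GenerationError`.  Identical
seed and configuration give byte-identical output.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneModel
from .classify import SLQSRecord, classify_hits
from .folding import DEFAULT_FOLD_PARAMS, FoldParams, fold_stem_loop, passes_screen
from .io import SequenceRecord
from .scanner import DEFAULT_SCAN_PARAMS, ScanParams, revcomp, scan_both_strands

__all__ = [
    "SyntheticConfig",
    "PlantedMotif",
    "SyntheticTruth",
    "GenerationError",
    "generate_synthetic_genome",
    "truth_to_bed",
]

CAT_SLQS = "SLQS"
CAT_PQS7 = "PQS_L7"
CAT_DECOY_NC = "decoy_no_complement"
CAT_DECOY_3T = "decoy_three_tract"
CAT_DECOY_CSTRAND = "decoy_c_strand"

_MAX_TRIES = 200
_PAD = 10  # flank used when self-checking an excised motif
_MIN_SPACER = 30  # no cross-motif hit is possible (> max_loop + tract slack)


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    length: int = 1_000_000
    n_slqs: int = 20
    n_pqs7: int = 10
    n_decoys: int = 30  # split as evenly as possible across the 3 categories
    n_genes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.length, self.n_slqs, self.n_pqs7, self.n_decoys, self.n_genes) < 0:
            raise ValueError("config counts must be >= 0")


@dataclass(frozen=True)
class PlantedMotif:
    category: str
    start: int
    end: int
    strand: str
    expected_stemloops: int = 0

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class SyntheticTruth:
    planted_slqs: tuple[PlantedMotif, ...]
    planted_pqs7: tuple[PlantedMotif, ...]
    decoys: tuple[PlantedMotif, ...]

    @property
    def all_motifs(self) -> tuple[PlantedMotif, ...]:
        return self.planted_slqs + self.planted_pqs7 + self.decoys


# ------------------------------------------------------------- raw sequence

_BASES = np.array(list("ACGT"))
_BG_PROBS = np.array([0.30, 0.20, 0.20, 0.30])  # G-poor-ish background


def _break_runs(arr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Destroy every G- or C-run of >= 3 nt by substituting every third base."""
    s = "".join(arr)
    for m in re.finditer(r"G{3,}|C{3,}", s):
        for pos in range(m.start() + 2, m.end(), 3):
            arr[pos] = "AT"[rng.integers(2)]
    return arr


def _spacer(rng: np.random.Generator, n: int) -> str:
    arr = rng.choice(_BASES, size=n, p=_BG_PROBS)
    arr = _break_runs(arr, rng)
    arr[0] = "T"
    arr[-1] = "T"
    return "".join(arr)


def _safe_fragment(rng: np.random.Generator, n: int, forbid_edge_g: bool = True) -> str:
    """Random fragment without G/C runs of >= 3 and (optionally) no G at the edges."""
    for _ in range(_MAX_TRIES):
        s = "".join(rng.choice(_BASES, size=n, p=np.array([0.3, 0.2, 0.2, 0.3])))
        if re.search(r"G{3}|C{3}", s):
            continue
        if forbid_edge_g and n > 0 and (s[0] == "G" or s[-1] == "G"):
            continue
        return s
    raise GenerationError(f"could not draw a safe fragment of {n} nt")


def _extension(tract_len: int) -> int:
    return min(max(tract_len - 3, 0), 3)


# ------------------------------------------------------------ motif builders

def _designed_long_loop(rng: np.random.Generator, ext5: int, ext3: int) -> str:
    """A raw long loop (11-20 nt) containing a planted stem that passes the screen."""
    for _ in range(_MAX_TRIES):
        raw_len = int(rng.integers(11, 21))
        ext_len = raw_len + ext5 + ext3
        arm_min = max(4, math.ceil(ext_len / 4))
        arm_max = (raw_len - 3) // 2
        if arm_min > arm_max:
            continue
        arm_len = int(rng.integers(arm_min, arm_max + 1))
        hp_len = 3
        slack = raw_len - 2 * arm_len - hp_len
        pre_len = int(rng.integers(0, slack + 1))  # randomized stem offset
        post_len = slack - pre_len
        arm = _safe_fragment(rng, arm_len, forbid_edge_g=False)
        loop = (
            _safe_fragment(rng, pre_len) if pre_len else ""
        ) + arm + _safe_fragment(rng, hp_len, forbid_edge_g=False) + revcomp(arm) + (
            _safe_fragment(rng, post_len) if post_len else ""
        )
        if len(loop) != raw_len or re.search(r"G{3}|C{3}", loop):
            continue
        if loop[0] == "G" or loop[-1] == "G":
            continue
        pred = fold_stem_loop("G" * ext5 + loop + "G" * ext3)
        if passes_screen(pred).passed:
            return loop
    raise GenerationError("could not design a screened long loop")


def _check_motif(motif: str, category: str, expected_sl: int) -> bool:
    """Excise with flanks and run the real scanner + classifier."""
    rec = SequenceRecord("check", "T" * _PAD + motif + "T" * _PAD)
    hits = scan_both_strands(rec)
    pqs7, slqs, rejected = classify_hits(hits, rec)
    if category == CAT_SLQS:
        return any(s.n_stemloops == expected_sl and s.hit.strand == "+" for s in slqs)
    if category == CAT_PQS7:
        return bool(pqs7) and not slqs
    if category == CAT_DECOY_NC:
        return not slqs and bool(rejected)
    if category == CAT_DECOY_3T:
        return not hits
    if category == CAT_DECOY_CSTRAND:
        return any(s.hit.strand == "-" for s in slqs) and not any(
            s.hit.strand == "+" for s in slqs
        )
    raise ValueError(category)


def _build_slqs(rng: np.random.Generator, tract_choices=(3, 4, 5, 6)) -> tuple[str, int]:
    for _ in range(_MAX_TRIES):
        tracts = [int(rng.choice(tract_choices)) for _ in range(4)]
        n_long = int(rng.integers(1, 4))
        long_idx = sorted(rng.choice(3, size=n_long, replace=False))
        loops = []
        for i in range(3):
            if i in long_idx:
                loops.append(
                    _designed_long_loop(rng, _extension(tracts[i]), _extension(tracts[i + 1]))
                )
            else:
                loops.append(_safe_fragment(rng, int(rng.integers(1, 8))))
        motif = "".join(
            "G" * tracts[i] + (loops[i] if i < 3 else "") for i in range(4)
        )
        if _check_motif(motif, CAT_SLQS, n_long):
            return motif, n_long
    raise GenerationError("could not build a recoverable planted SLQS")


def _build_pqs7(rng: np.random.Generator) -> str:
    for _ in range(_MAX_TRIES):
        tracts = [int(rng.integers(3, 7)) for _ in range(4)]
        loops = [_safe_fragment(rng, int(rng.integers(1, 8))) for _ in range(3)]
        motif = "".join("G" * tracts[i] + (loops[i] if i < 3 else "") for i in range(4))
        if _check_motif(motif, CAT_PQS7, 0):
            return motif
    raise GenerationError("could not build a recoverable planted PQS_L7")


def _build_decoy_nc(rng: np.random.Generator) -> str:
    """Four G3 tracts with one long loop of shuffled, complementarity-free content."""
    for _ in range(_MAX_TRIES):
        long_pos = int(rng.integers(0, 3))
        loops = []
        for i in range(3):
            if i == long_pos:
                loops.append(_safe_fragment(rng, int(rng.integers(11, 21))))
            else:
                loops.append(_safe_fragment(rng, int(rng.integers(1, 8))))
        motif = "".join("GGG" + (loops[i] if i < 3 else "") for i in range(4))
        if _check_motif(motif, CAT_DECOY_NC, 0):
            return motif
    raise GenerationError("could not build a complementarity-free decoy")


def _build_decoy_3t(rng: np.random.Generator) -> str:
    for _ in range(_MAX_TRIES):
        tracts = [int(rng.integers(3, 7)) for _ in range(3)]
        loops = [_safe_fragment(rng, int(rng.integers(1, 8))) for _ in range(2)]
        motif = "".join(
            "G" * tracts[i] + (loops[i] if i < 2 else "") for i in range(3)
        )
        if _check_motif(motif, CAT_DECOY_3T, 0):
            return motif
    raise GenerationError("could not build a three-tract decoy")


def _build_decoy_cstrand(rng: np.random.Generator) -> tuple[str, int]:
    for _ in range(_MAX_TRIES):
        motif, n_long = _build_slqs(rng, tract_choices=(3, 4))
        rc = revcomp(motif)
        if _check_motif(rc, CAT_DECOY_CSTRAND, n_long):
            return rc, n_long
    raise GenerationError("could not build a C-strand decoy")


# --------------------------------------------------------------- gene models

def _toy_genes(rng: np.random.Generator, n: int, length: int, chrom: str) -> list[GeneModel]:
    genes = []
    for gi in range(n):
        tx_len = int(rng.integers(2_000, 20_001))
        tx_start = int(rng.integers(2_100, max(length - tx_len - 2_100, 2_101)))
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 5))
        # alternate exon/intron blocks spanning the transcript
        cuts = np.sort(rng.choice(np.arange(100, tx_len - 100), size=2 * n_exons - 2, replace=False))
        bounds = [0, *cuts.tolist(), tx_len]
        exons = tuple(
            (tx_start + bounds[2 * k], tx_start + bounds[2 * k + 1]) for k in range(n_exons)
        )
        first_s, first_e = exons[0]
        last_s, last_e = exons[-1]
        cds_start = int(rng.integers(first_s + 1, first_e))
        cds_end = int(rng.integers(last_s + 1, last_e))
        genes.append(
            GeneModel(
                tx_id=f"SYNT{gi:04d}",
                gene_symbol=f"SYNG{gi:04d}",
                seq_name=chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_start + tx_len,
                cds_start=cds_start,
                cds_end=cds_end,
                exons=exons,
            )
        )
    return genes


# ------------------------------------------------------------------ assembly

def generate_synthetic_genome(
    config: SyntheticConfig,
) -> tuple[SequenceRecord, SyntheticTruth, list[GeneModel]]:
    """Assemble a synthetic chromosome with planted, self-verified motifs.

    Returns (sequence record, ground truth, toy gene models).
    """
    rng = np.random.default_rng(config.seed)
    chrom = "synth1"

    pieces: list[tuple[str, str, int]] = []  # (sequence, category, expected SL)
    for _ in range(config.n_slqs):
        motif, n_long = _build_slqs(rng)
        pieces.append((motif, CAT_SLQS, n_long))
    for _ in range(config.n_pqs7):
        pieces.append((_build_pqs7(rng), CAT_PQS7, 0))
    base, extra = divmod(config.n_decoys, 3)
    n_nc, n_3t, n_cs = base + (extra > 0), base + (extra > 1), base
    for _ in range(n_nc):
        pieces.append((_build_decoy_nc(rng), CAT_DECOY_NC, 0))
    for _ in range(n_3t):
        pieces.append((_build_decoy_3t(rng), CAT_DECOY_3T, 0))
    for _ in range(n_cs):
        motif, n_long = _build_decoy_cstrand(rng)
        pieces.append((motif, CAT_DECOY_CSTRAND, n_long))

    order = rng.permutation(len(pieces))
    pieces = [pieces[i] for i in order]

    motif_total = sum(len(p[0]) for p in pieces)
    n_spacers = len(pieces) + 1
    remaining = config.length - motif_total
    if remaining < _MIN_SPACER * n_spacers:
        raise GenerationError(
            f"genome length {config.length} too small for {len(pieces)} motifs"
        )
    extra_space = rng.multinomial(remaining - _MIN_SPACER * n_spacers,
                                  np.full(n_spacers, 1.0 / n_spacers))
    spacer_lens = extra_space + _MIN_SPACER

    parts = [_spacer(rng, int(spacer_lens[0]))]
    pos = int(spacer_lens[0])
    slqs, pqs7, decoys = [], [], []
    for k, (motif, category, n_sl) in enumerate(pieces):
        planted = PlantedMotif(
            category=category,
            start=pos,
            end=pos + len(motif),
            strand="-" if category == CAT_DECOY_CSTRAND else "+",
            expected_stemloops=n_sl,
        )
        if category == CAT_SLQS:
            slqs.append(planted)
        elif category == CAT_PQS7:
            pqs7.append(planted)
        else:
            decoys.append(planted)
        parts.append(motif)
        pos += len(motif)
        parts.append(_spacer(rng, int(spacer_lens[k + 1])))
        pos += int(spacer_lens[k + 1])

    seq = "".join(parts)
    assert len(seq) == config.length
    record = SequenceRecord(name=chrom, seq=seq)
    truth = SyntheticTruth(
        planted_slqs=tuple(slqs), planted_pqs7=tuple(pqs7), decoys=tuple(decoys)
    )
    for m in truth.all_motifs:
        if not (0 <= m.start < m.end <= config.length):
            raise GenerationError("planted interval outside genome bounds")
    genes = _toy_genes(rng, config.n_genes, config.length, chrom) if config.length > 25_000 else []
    return record, truth, genes


def truth_to_bed(truth: SyntheticTruth, path) -> None:
    """Ground truth as BED6+1 (extra column: category)."""
    with open(path, "w") as fh:
        for i, m in enumerate(truth.all_motifs):
            fh.write(
                f"synth1\t{m.start}\t{m.end}\tplanted{i:04d}\t0\t{m.strand}\t{m.category}\n"
            )
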