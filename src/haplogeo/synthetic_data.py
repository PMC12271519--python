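"""Synthetic inputs: the published-table fixture, spatial simulations and
neutral coalescent samples.

Three generators, all deterministic given a seed:

* :func:`make_study_fixture` rebuilds the hedgehog study's 102-sample,
  801-base concatenated alignment from its printed variable-site patterns
  and haplotype frequencies, embedding the seven variable columns (two in
  cytochrome b, five in the control region, including a two-base indel)
  in a seed-generated invariant background. Invariant columns affect no
  implemented statistic except the site count L, so the background base
  content is arbitrary. Samples are also placed at synthetic sampling
  sites whose occupancy mirrors the study's reported structure (H1 at 4
  sites, H2 at 29, H3 concentrated at 6, eight sites with >= 3 samples);
  the site memberships and coordinates themselves are synthetic.

* :func:`simulate_spatial_dataset` draws sampling sites uniformly in a
  box and assigns haplotype labels with a tunable clustering parameter
  ``c`` for one focal haplotype: with probability ``c`` a focal carrier
  is placed at one of a small designated subset of tightly clustered
  sites, otherwise uniformly. ``c = 0`` makes assignment exchangeable
  across sites (the null of the spatial tests); ``c = 1`` confines the
  focal haplotype to the tight subset.

* :func:`coalescent_sample` draws from the standard neutral (Kingman)
  coalescent with infinite-sites mutations, either Poisson-distributed at
  rate theta/2 per branch (``THETA``) or exactly S mutations placed
  multinomially by branch length (``FIXED_S``). This is the replicate
  generator behind the neutrality-test p-values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqdata import AlignedSequence, Locus
from .spatial import SampleRecord

__all__ = [
    "SEQUENCE_OFFSET",
    "CYTB_LENGTH",
    "CR_LENGTH",
    "TOTAL_LENGTH",
    "VARIABLE_POSITIONS",
    "HAPLOTYPE_PATTERNS",
    "HAPLOTYPE_COUNTS",
    "StudyFixture",
    "SimConfig",
    "CoalescentSample",
    "make_study_fixture",
    "write_fixture",
    "simulate_spatial_dataset",
    "coalescent_sample",
]

# Reconstruction constants: the study's variable-site table and haplotype
# frequencies. Reference positions follow the hedgehog mitochondrial
# genome numbering; the concatenated alignment spans 14771..15571.
SEQUENCE_OFFSET = 14_771
CYTB_LENGTH = 376
CR_LENGTH = 425
TOTAL_LENGTH = CYTB_LENGTH + CR_LENGTH  # 801

VARIABLE_POSITIONS = (14_910, 15_079, 15_158, 15_159, 15_205, 15_222, 15_560)

# One character per variable position, in VARIABLE_POSITIONS order.
HAPLOTYPE_PATTERNS: dict[str, str] = {
    "H1": "CA--CAC",
    "H2": "CA--CGC",
    "H3": "CAATCAC",
    "H4": "CA--CGT",
    "H5": "CA--TGC",
    "H6": "CGATCAC",
    "H7": "TA--CGC",
}

HAPLOTYPE_COUNTS: dict[str, int] = {
    "H1": 8, "H2": 52, "H3": 33, "H4": 3, "H5": 4, "H6": 1, "H7": 1,
}

# Synthetic site layout (site memberships are NOT published; this layout
# only honours the reported totals: H1 at 4 sites, H2 at 29 sites, H3 at
# 6 sites, exactly 8 sites holding >= 3 samples). Each item: (site tag,
# haplotype, number of samples).
_SITE_PLAN: tuple[tuple[str, str, int], ...] = (
    # the eight multi-sample (>= 3) sites
    ("RegentsPark", "H3", 20), ("RegentsPark", "H2", 1),
    ("Hampstead", "H3", 5), ("Hampstead", "H2", 2),
    ("Barnes", "H1", 4),
    ("LeeValley", "H2", 3),
    ("Ware", "H2", 3), ("Ware", "H5", 1),
    ("StAlbans", "H2", 3), ("StAlbans", "H4", 1),
    ("Hertford", "H2", 3),
    ("Epping", "H2", 2), ("Epping", "H6", 1),
    # H3's four remaining sites (pairs, < 3 samples each)
    ("Camden", "H3", 2), ("Islington", "H3", 2),
    ("Finchley", "H3", 2), ("Watford", "H3", 2),
    # H1's three remaining sites
    ("Richmond", "H1", 2), ("Kingston", "H1", 1), ("Sutton", "H1", 1),
    # remaining rare haplotypes
    ("Dartford", "H5", 1), ("Margate", "H5", 1), ("Ely", "H5", 1),
    ("Romford", "H4", 1), ("Slough", "H4", 1),
    ("Croydon", "H7", 1),
    # H2 filler: 13 pair-sites + 9 singleton sites -> 29 H2 sites total
    *[(f"TownP{i:02d}", "H2", 2) for i in range(1, 14)],
    *[(f"TownS{i:02d}", "H2", 1) for i in range(1, 10)],
)

# Central-London-like sites kept inside a small sub-box so that the most
# concentrated haplotype (H3) is genuinely spatially clustered.
_CENTRAL_SITES = {
    "RegentsPark", "Hampstead", "Barnes", "LeeValley",
    "Camden", "Islington", "Finchley", "Richmond",
}


@dataclass(frozen=True)
class StudyFixture:
    """Reconstructed study input bundle."""

    alignment: list[AlignedSequence]        # 102 CONCAT sequences, 801 bases
    cytb: list[AlignedSequence]             # the same samples, first 376 bases
    cr: list[AlignedSequence]               # last 425 bases
    records: list[SampleRecord]             # synthetic site assignment
    label_map: dict[str, str]               # canonical sequence -> H1..H7
    counts: dict[str, int]
    seed: int


def _background(rng: np.random.Generator) -> np.ndarray:
    return rng.choice(np.array(list("ACGT")), size=TOTAL_LENGTH)


def make_study_fixture(seed: int = 0) -> StudyFixture:
    """Rebuild the 102 x 801 study alignment plus synthetic site metadata.

    The seven variable columns carry exactly the published state patterns
    (identical for every seed); the invariant background is drawn from a
    uniform base distribution per seed.
    """
    rng = np.random.default_rng(seed)
    background = _background(rng)
    col_of = {p: p - SEQUENCE_OFFSET for p in VARIABLE_POSITIONS}

    hap_seq: dict[str, str] = {}
    for hap, pattern in HAPLOTYPE_PATTERNS.items():
        bases = background.copy()
        for pos, state in zip(VARIABLE_POSITIONS, pattern):
            bases[col_of[pos]] = state
        hap_seq[hap] = "".join(bases)

    # expand the site plan into per-sample assignments
    plan = [(site, hap) for site, hap, k in _SITE_PLAN for _ in range(k)]
    by_hap: dict[str, list[str]] = {h: [] for h in HAPLOTYPE_COUNTS}
    for site, hap in plan:
        by_hap[hap].append(site)
    for hap, count in HAPLOTYPE_COUNTS.items():
        if len(by_hap[hap]) != count:
            raise AssertionError(
                f"site plan allots {len(by_hap[hap])} samples to {hap}, "
                f"expected {count}"
            )

    # site coordinates: central sites in a 15x15 km sub-box, others spread
    # over a 120x120 km box
    site_names = sorted({site for site, _, _ in _SITE_PLAN})
    coords: dict[str, tuple[float, float]] = {}
    for name in site_names:
        if name in _CENTRAL_SITES:
            xy = rng.uniform([50.0, 50.0], [65.0, 65.0])
        else:
            xy = rng.uniform([0.0, 0.0], [120.0, 120.0])
        coords[name] = (float(xy[0]), float(xy[1]))

    alignment: list[AlignedSequence] = []
    records: list[SampleRecord] = []
    idx = 0
    for hap in HAPLOTYPE_COUNTS:  # insertion order H1..H7
        for site in by_hap[hap]:
            idx += 1
            sid = f"EE{idx:03d}"
            alignment.append(
                AlignedSequence(sid, Locus.CONCAT, hap_seq[hap], SEQUENCE_OFFSET)
            )
            x, y = coords[site]
            records.append(SampleRecord(sid, hap, site, x, y))

    cytb = [
        AlignedSequence(s.sample_id, Locus.CYTB, s.bases[:CYTB_LENGTH], SEQUENCE_OFFSET)
        for s in alignment
    ]
    cr = [
        AlignedSequence(
            s.sample_id, Locus.CR, s.bases[CYTB_LENGTH:], SEQUENCE_OFFSET + CYTB_LENGTH
        )
        for s in alignment
    ]
    label_map = {seq: hap for hap, seq in hap_seq.items()}
    return StudyFixture(
        alignment=alignment,
        cytb=cytb,
        cr=cr,
        records=records,
        label_map=label_map,
        counts=dict(HAPLOTYPE_COUNTS),
        seed=seed,
    )


def write_fixture(fixture: StudyFixture, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture as a FASTA + metadata CSV input bundle."""
    from .seqdata import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "alignment.fasta"
    meta = outdir / "samples.csv"
    write_fasta(fixture.alignment, fasta)
    with open(meta, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "site_id", "x_km", "y_km"])
        for r in fixture.records:
            w.writerow([r.sample_id, r.site_id, f"{r.x_km:.6f}", f"{r.y_km:.6f}"])
    return {"fasta": fasta, "metadata": meta}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a spatially structured synthetic dataset.

    ``haplotype_counts`` is the exact frequency vector (one label per
    entry, ``H1``..); ``focal`` indexes the clustered haplotype;
    ``clustering_c`` in [0, 1] is the probability a focal carrier is
    placed at one of the ``n_tight_sites`` designated sites, which sit in
    a ``tight_fraction``-scaled corner of the ``box_km`` sampling box.
    """

    haplotype_counts: tuple[int, ...] = (30, 40, 15, 10, 5)
    focal: int = 0
    clustering_c: float = 0.0
    n_sites: int = 30
    n_tight_sites: int = 3
    box_km: tuple[float, float] = (100.0, 100.0)
    tight_fraction: float = 0.1
    seed: int = 0

    @property
    def focal_label(self) -> str:
        return f"H{self.focal + 1}"


def simulate_spatial_dataset(cfg: SimConfig) -> list[SampleRecord]:
    """Draw sites and spatially assign haplotype labels per `cfg`."""
    if not 0.0 <= cfg.clustering_c <= 1.0:
        raise ValueError("clustering_c must lie in [0, 1]")
    if not 0 < cfg.n_tight_sites <= cfg.n_sites:
        raise ValueError("n_tight_sites must be in 1..n_sites")
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.box_km
    # tight sites in the scaled corner sub-box, the rest across the box
    tight = rng.uniform(
        [0.0, 0.0], [w * cfg.tight_fraction, h * cfg.tight_fraction],
        size=(cfg.n_tight_sites, 2),
    )
    broad = rng.uniform(
        [0.0, 0.0], [w, h], size=(cfg.n_sites - cfg.n_tight_sites, 2)
    )
    xy = np.vstack([tight, broad])
    site_ids = [f"S{i + 1:02d}" for i in range(cfg.n_sites)]

    labels = [
        f"H{j + 1}" for j, c in enumerate(cfg.haplotype_counts) for _ in range(c)
    ]
    records: list[SampleRecord] = []
    for i, lab in enumerate(labels):
        if lab == cfg.focal_label and rng.random() < cfg.clustering_c:
            site = int(rng.integers(0, cfg.n_tight_sites))
        else:
            site = int(rng.integers(0, cfg.n_sites))
        records.append(
            SampleRecord(
                f"ind{i + 1:03d}", lab, site_ids[site],
                float(xy[site, 0]), float(xy[site, 1]),
            )
        )
    return records


@dataclass(frozen=True)
class CoalescentSample:
    """Infinite-sites sample from the standard neutral coalescent.

    ``patterns`` is an (n, S) 0/1 matrix: entry [i, j] is 1 when sample i
    carries the derived state at segregating site j. ``positions`` are the
    mutated lattice positions (1-based over ``lattice`` sites).
    """

    n: int
    conditioning: str
    patterns: np.ndarray
    positions: tuple[int, ...]
    total_branch_length: float


def _kingman_branches(
    n: int, rng: np.random.Generator
) -> list[tuple[frozenset[int], float]]:
    """Simulate a Kingman genealogy; return (leaf set, branch length) for
    every branch below the root. Time is in units of 2N generations."""
    active: list[tuple[frozenset[int], float]] = [
        (frozenset([i]), 0.0) for i in range(n)
    ]
    done: list[tuple[frozenset[int], float]] = []
    while len(active) > 1:
        j = len(active)
        t = rng.exponential(1.0 / (j * (j - 1) / 2.0))
        active = [(leaves, length + t) for leaves, length in active]
        i1, i2 = sorted(rng.choice(j, size=2, replace=False))
        a = active.pop(i2)
        b = active.pop(i1)
        done.extend([a, b])
        active.append((a[0] | b[0], 0.0))
    return done


def coalescent_sample(
    n: int,
    conditioning: str = "FIXED_S",
    value: float = 5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    lattice: int = 801,
) -> CoalescentSample:
    """One neutral coalescent replicate.

    ``THETA``: mutation count ~ Poisson(theta * T / 2) with T the total
    branch length (so E[S] = theta * a1(n)); ``FIXED_S``: exactly S
    mutations. Each mutation lands on a branch with probability
    proportional to its length and is assigned a distinct position on the
    ``lattice`` (collisions redrawn -- infinite-sites over a finite map).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if conditioning not in ("FIXED_S", "THETA"):
        raise ValueError(f"unknown conditioning: {conditioning}")
    if rng is None:
        rng = np.random.default_rng(seed)
    branches = _kingman_branches(n, rng)
    lengths = np.array([b[1] for b in branches])
    total = float(lengths.sum())
    if conditioning == "THETA":
        if value <= 0:
            raise ValueError("theta must be positive")
        n_mut = int(rng.poisson(value * total / 2.0))
    else:
        if value < 0 or int(value) != value:
            raise ValueError("S must be a non-negative integer")
        n_mut = int(value)
    patterns = np.zeros((n, n_mut), dtype=np.int8)
    positions: list[int] = []
    used: set[int] = set()
    if n_mut:
        probs = lengths / total
        hit = rng.choice(len(branches), size=n_mut, p=probs)
        for j, b in enumerate(hit):
            for leaf in branches[b][0]:
                patterns[leaf, j] = 1
            while True:
                pos = int(rng.integers(1, lattice + 1))
                if pos not in used or len(used) >= lattice:
                    used.add(pos)
                    break
            positions.append(pos)
    return CoalescentSample(
        n=n,
        conditioning=conditioning,
        patterns=patterns,
        positions=tuple(positions),
        total_branch_length=total,
    )
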