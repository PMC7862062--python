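"""Ground-truth synthetic data generators.

Three generators emulate the statistical structure of the assays the
pipeline analyses:

* **Ψ-seq RT-termination reads** — cDNA synthesis proceeds 3′→5′ from a
  uniformly placed start; at each pseudouridylated site crossed the reverse
  transcriptase terminates with probability ``f·e`` (site stoichiometry
  times termination efficiency), at every other nucleotide with a small
  background rate ``b``; otherwise the read ends where the fragment does
  (truncated-geometric length). A terminated read's reference 5′-start
  equals the Ψ position (offset 0) or the next base (offset 1, the
  CMC-adduct convention).
* **Paired snoRNA counts** — negative-binomial counts for C/D- and
  H/ACA-box snoRNAs over matched tumour/normal pairs, with a designated
  up-regulated subset at a known fold change and a per-patient pairing
  effect shared within each pair.
* **Pooled CRISPR screen counts** — per-gRNA abundance evolves as
  ``(1+s)^doublings`` under a per-target fitness ``s``; sequencing draws
  are multinomial at fixed depth per (timepoint, replicate) sample.

All generators derive their random streams from one master seed via fixed
labels (see :mod:`psiforge._rng`), so identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from psiforge import io
from psiforge._rng import child_rng

_BACKGROUND_CAP = 0.05  # background RT stops are rare by construction

ReadTuple = tuple[str, int, int, str]  # molecule, 5'-start, 3'-end (1-based incl.), name


# ---------------------------------------------------------------------------
# Ψ-seq termination reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsiSite:
    """One pseudouridylated position with its guide snoRNA."""

    molecule: str
    position: int  # 1-based
    stoichiometry: float  # fraction of molecules modified, f in [0, 1]
    guide: str = ""


@dataclass
class SimPsiConfig:
    """Parameters of the Ψ-seq read generator.

    Parameters
    ----------
    molecule_lengths
        Mock rRNA molecules (e.g. ``{"18S-like": 600}``), each ≥ 200 nt.
    sites
        Ψ sites; positions are 1-based and distinct per molecule.
    termination_efficiency
        Probability ``e`` that the RT stops at a modified site it crosses.
    background_stop_rate
        Per-nucleotide stop probability ``b`` at non-site positions
        (capped at 0.05).
    mean_read_length
        Mean of the (truncated) geometric cDNA length distribution, nt.
    coverage
        Target mean per-base coverage; reads are emitted until the total
        simulated bases reach ``coverage × molecule length``.
    termination_offset
        0 → a terminated read starts at the Ψ position itself;
        1 → it starts one base 3′ of it (stop before incorporation).
    """

    molecule_lengths: dict[str, int]
    sites: list[PsiSite]
    termination_efficiency: float = 0.9
    background_stop_rate: float = 0.01
    mean_read_length: float = 80.0
    coverage: float = 200.0
    termination_offset: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        for name, length in self.molecule_lengths.items():
            if length < 200:
                errors.append(f"molecule {name!r}: length {length} < 200 nt")
        if not 0.0 <= self.termination_efficiency <= 1.0:
            errors.append(f"termination_efficiency {self.termination_efficiency} outside [0, 1]")
        if not 0.0 <= self.background_stop_rate <= _BACKGROUND_CAP:
            errors.append(
                f"background_stop_rate {self.background_stop_rate} outside [0, {_BACKGROUND_CAP}]"
            )
        if self.mean_read_length < 1:
            errors.append("mean_read_length must be >= 1 nt")
        if self.termination_offset not in (0, 1):
            errors.append(f"termination_offset must be 0 or 1, got {self.termination_offset}")
        seen: set[tuple[str, int]] = set()
        for site in self.sites:
            key = (site.molecule, site.position)
            if key in seen:
                errors.append(f"duplicate site {site.molecule}:{site.position}")
            seen.add(key)
            if site.molecule not in self.molecule_lengths:
                errors.append(f"site {site.molecule}:{site.position}: unknown molecule")
            elif not 1 <= site.position <= self.molecule_lengths[site.molecule]:
                errors.append(
                    f"site {site.molecule}:{site.position} exceeds molecule length "
                    f"{self.molecule_lengths[site.molecule]}"
                )
            if not 0.0 <= site.stoichiometry <= 1.0:
                errors.append(
                    f"site {site.molecule}:{site.position}: stoichiometry "
                    f"{site.stoichiometry} outside [0, 1]"
                )
        if errors:
            raise ValueError("invalid SimPsiConfig: " + "; ".join(errors))


def make_reference(config: SimPsiConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Build reference sequences and the Ψ-site annotation table.

    Sequences are random ACGT with ``T`` forced at every Ψ position. Returns
    ``(sequences, site_table)`` where the site table has columns
    ``site_id, molecule, position, guides``.
    """
    rng = child_rng(config.seed, "reference")
    sequences: dict[str, str] = {}
    for name, length in config.molecule_lengths.items():
        bases = rng.choice(np.array(list("ACGT")), size=length)
        for site in config.sites:
            if site.molecule == name:
                bases[site.position - 1] = "T"
        sequences[name] = "".join(bases)
    rows = [
        {
            "site_id": f"{s.molecule}:{s.position}",
            "molecule": s.molecule,
            "position": s.position,
            "guides": s.guide,
        }
        for s in sorted(config.sites, key=lambda s: (s.molecule, s.position))
    ]
    return sequences, pd.DataFrame(rows, columns=["site_id", "molecule", "position", "guides"])


def _simulate_molecule_reads(
    rng: np.random.Generator,
    molecule: str,
    length: int,
    site_pos: np.ndarray,
    site_hazard: np.ndarray,
    b: float,
    mean_len: float,
    target_bases: float,
    offset: int,
    sample_id: str,
) -> list[ReadTuple]:
    # Scan segment-wise: the run of non-site bases between consecutive sites
    # survives background with prob (1-b)^gap, so the first background stop
    # within a run is geometric. Distributionally identical to a per-base
    # Bernoulli walk, but O(sites-per-read) instead of O(read length).
    geom_p = 1.0 / mean_len
    reads: list[ReadTuple] = []
    bases = 0.0
    idx = 0
    site_pos = np.asarray(site_pos, dtype=int)
    order = np.argsort(site_pos)
    site_pos = site_pos[order]
    site_hazard = np.asarray(site_hazard, dtype=float)[order]
    while bases < target_bases:
        t = int(rng.integers(1, length + 1))  # 3'-start (first base synthesised)
        nat_len = min(t, int(rng.geometric(geom_p)))
        e0 = t - nat_len + 1
        five = e0
        stopped_at_site = False
        cur = t
        hi = int(np.searchsorted(site_pos, t, side="right"))
        lo = int(np.searchsorted(site_pos, e0, side="left"))
        done = False
        for j in range(hi - 1, lo - 1, -1):
            p = int(site_pos[j])
            gap = cur - p  # non-site bases scanned before reaching p
            if b > 0.0 and gap > 0:
                d = int(rng.geometric(b))
                if d <= gap:
                    five = cur - d + 1
                    done = True
                    break
            if site_hazard[j] > 0.0 and rng.random() < site_hazard[j]:
                five = p
                stopped_at_site = True
                done = True
                break
            cur = p - 1
        if not done:
            tail = cur - e0 + 1
            if b > 0.0 and tail > 0:
                d = int(rng.geometric(b))
                if d <= tail:
                    five = cur - d + 1
        if stopped_at_site and offset == 1:
            five += 1  # stop *before* the modified base
            if five > t:
                continue  # zero-length cDNA; nothing to sequence
        reads.append((molecule, five, t, f"{sample_id}:{molecule}:{len(reads)}"))
        bases += t - five + 1
    return reads


def simulate_termination_reads(
    config: SimPsiConfig, sample_id: str, stoichiometry_override: dict[tuple[str, int], float] | None = None
) -> tuple[list[ReadTuple], pd.DataFrame]:
    """Simulate mapped Ψ-seq reads for one sample.

    Returns ``(reads, truth)`` where ``truth`` lists the per-site true
    stoichiometry used for this sample. ``stoichiometry_override`` replaces
    the configured ``f`` for selected ``(molecule, position)`` keys — used
    to give paired samples shared sites at different modification levels.
    Reads are coordinate-sorted and ready for :func:`psiforge.io.write_sam`.
    """
    override = stoichiometry_override or {}
    reads: list[ReadTuple] = []
    truth_rows = []
    for molecule, length in config.molecule_lengths.items():
        rng = child_rng(config.seed, f"psi-reads/{sample_id}/{molecule}")
        sites = [s for s in config.sites if s.molecule == molecule]
        fs = np.array(
            [
                float(np.clip(override.get((s.molecule, s.position), s.stoichiometry), 0.0, 1.0))
                for s in sites
            ]
        )
        pos = np.array([s.position for s in sites], dtype=int)
        hazard = fs * config.termination_efficiency
        target = config.coverage * length
        if target <= 0:
            warnings.warn(f"zero coverage requested for {molecule}; emitting no reads")
            continue
        reads.extend(
            _simulate_molecule_reads(
                rng, molecule, length, pos, hazard, config.background_stop_rate,
                config.mean_read_length, target, config.termination_offset, sample_id,
            )
        )
        for s, f in zip(sites, fs):
            truth_rows.append(
                {
                    "sample": sample_id,
                    "site_id": f"{s.molecule}:{s.position}",
                    "molecule": s.molecule,
                    "position": s.position,
                    "stoichiometry": f,
                    "guide": s.guide,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample", "site_id", "molecule", "position", "stoichiometry", "guide"],
    )
    return io.sort_reads(reads), truth


def simulate_paired_psi_samples(
    config: SimPsiConfig,
    n_pairs: int,
    shift_a: dict[tuple[str, int], float] | None = None,
    pair_jitter_sd: float = 0.0,
) -> tuple[dict[str, list[ReadTuple]], pd.DataFrame]:
    """Simulate matched condition-A/condition-B Ψ-seq sample pairs.

    Condition A (e.g. tumour) adds ``shift_a`` to the configured
    stoichiometry at the listed sites; a per-pair jitter (shared by both
    members, clipped into [0, 1]) emulates patient-level variation. Returns
    ``({sample_id: reads}, design)`` with design columns
    ``unit, sample_a, sample_b``.
    """
    shift_a = shift_a or {}
    rng = child_rng(config.seed, "psi-pair-jitter")
    out: dict[str, list[ReadTuple]] = {}
    design_rows = []
    for i in range(1, n_pairs + 1):
        jitter = {
            (s.molecule, s.position): float(rng.normal(0.0, pair_jitter_sd)) if pair_jitter_sd > 0 else 0.0
            for s in config.sites
        }
        fa = {
            k: float(np.clip(
                next(s.stoichiometry for s in config.sites if (s.molecule, s.position) == k)
                + jitter[k] + shift_a.get(k, 0.0), 0.0, 1.0))
            for k in jitter
        }
        fb = {
            k: float(np.clip(
                next(s.stoichiometry for s in config.sites if (s.molecule, s.position) == k)
                + jitter[k], 0.0, 1.0))
            for k in jitter
        }
        sid_a, sid_b = f"P{i}_A", f"P{i}_B"
        out[sid_a], _ = simulate_termination_reads(config, sid_a, stoichiometry_override=fa)
        out[sid_b], _ = simulate_termination_reads(config, sid_b, stoichiometry_override=fb)
        design_rows.append({"unit": f"P{i}", "sample_a": sid_a, "sample_b": sid_b})
    return out, pd.DataFrame(design_rows)


# ---------------------------------------------------------------------------
# Paired snoRNA counts
# ---------------------------------------------------------------------------

@dataclass
class SimCountConfig:
    """Parameters of the paired tumour/normal snoRNA count generator.

    ``cd_read_share`` / ``haca_read_share`` set the expected fraction of
    each sample's total mapped reads falling into the two snoRNA classes
    (the remainder stands for other RNA species); defaults mirror a lung
    tissue composition of 16% C/D-box and 4.4% H/ACA-box reads. The
    ``n_upregulated`` H/ACA snoRNAs with the largest simulated baselines
    carry ``fold_change`` in condition A (tumour).
    """

    n_cd: int = 40
    n_haca: int = 30
    n_pairs: int = 7
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1
    pair_effect_sd: float = 0.15
    n_upregulated: int = 9
    fold_change: float = 4.0
    total_mapped_reads: int = 2_000_000
    library_size_log_sd: float = 0.1
    cd_read_share: float = 0.16
    haca_read_share: float = 0.044
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.n_cd < 2 or self.n_haca < 2:
            errors.append("need at least 2 snoRNAs per class")
        if self.n_pairs < 3:
            errors.append("need >= 3 sample pairs for any downstream paired test")
        if self.fold_change <= 0:
            errors.append("fold_change must be > 0")
        if self.dispersion <= 0:
            errors.append("dispersion must be > 0")
        if self.n_upregulated > self.n_haca:
            errors.append("n_upregulated exceeds number of H/ACA snoRNAs")
        if self.total_mapped_reads <= 0:
            errors.append("total_mapped_reads must be > 0")
        if not 0 < self.cd_read_share + self.haca_read_share < 1:
            errors.append("class read shares must sum into (0, 1)")
        if errors:
            raise ValueError("invalid SimCountConfig: " + "; ".join(errors))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # Gamma-Poisson mixture: var = mu + dispersion * mu^2
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.asarray(mean) * dispersion)
    return rng.poisson(lam)


def simulate_snorna_counts(
    config: SimCountConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.DataFrame]:
    """Simulate a paired snoRNA count matrix with known ground truth.

    Returns ``(counts, total_mapped, design, truth)``:

    * ``counts`` — snoRNAs × samples integer DataFrame, samples named
      ``P{i}_T`` / ``P{i}_N``;
    * ``total_mapped`` — per-sample total mapped reads (snoRNA reads plus
      the other-RNA remainder);
    * ``design`` — columns ``unit, sample_a, sample_b`` (A = tumour);
    * ``truth`` — per snoRNA: class, upregulated flag, true fold change.
    """
    rng = child_rng(config.seed, "snorna-counts")
    names = [f"SNORD_{i:03d}" for i in range(1, config.n_cd + 1)] + [
        f"SNORA_{i:03d}" for i in range(1, config.n_haca + 1)
    ]
    classes = ["CD_box"] * config.n_cd + ["HACA_box"] * config.n_haca
    weights = rng.lognormal(0.0, config.baseline_log_sd, size=len(names))
    base = np.empty(len(names))
    cd = slice(0, config.n_cd)
    haca = slice(config.n_cd, None)
    base[cd] = weights[cd] / weights[cd].sum() * config.cd_read_share * config.total_mapped_reads
    base[haca] = (
        weights[haca] / weights[haca].sum() * config.haca_read_share * config.total_mapped_reads
    )
    # up-regulate the highest-expressed H/ACA snoRNAs so they are reliably detected
    haca_order = np.argsort(base[haca])[::-1] + config.n_cd
    upregulated = np.zeros(len(names), dtype=bool)
    upregulated[haca_order[: config.n_upregulated]] = True
    fc = np.where(upregulated, config.fold_change, 1.0)

    columns = {}
    size_factors = {}
    design_rows = []
    for i in range(1, config.n_pairs + 1):
        pair_effect = rng.lognormal(0.0, config.pair_effect_sd, size=len(names))
        for cond, mult in (("T", fc), ("N", 1.0)):
            sid = f"P{i}_{cond}"
            # library size varies per sample; the NB mean scales with it so
            # CPM fold changes stay centred on the configured fold change
            size = float(rng.lognormal(0.0, config.library_size_log_sd))
            size_factors[sid] = size
            mean = base * pair_effect * mult * size
            columns[sid] = _nb_draw(rng, mean, config.dispersion)
        design_rows.append({"unit": f"P{i}", "sample_a": f"P{i}_T", "sample_b": f"P{i}_N"})
    counts = pd.DataFrame(columns, index=pd.Index(names, name="snorna"))
    total_mapped = pd.Series(
        {sid: int(round(config.total_mapped_reads * size_factors[sid])) for sid in counts.columns},
        name="total_mapped_reads",
    )
    total_mapped = pd.Series(
        np.maximum(total_mapped.to_numpy(), counts.sum(axis=0).to_numpy()),
        index=counts.columns, name="total_mapped_reads",
    )
    design = pd.DataFrame(design_rows)
    truth = pd.DataFrame(
        {
            "snorna": names,
            "sno_class": classes,
            "upregulated": upregulated,
            "true_fold_change": fc,
        }
    )
    return counts, total_mapped, design, truth


def simulate_snorna_reads(
    annotation: pd.DataFrame,
    counts: pd.Series,
    n_background: int = 0,
    read_length: int = 60,
    chrom_length: int | None = None,
    seed: int = 0,
    sample_id: str = "S1",
) -> tuple[list[ReadTuple], dict[str, int]]:
    """Emit mapped reads realising a known per-snoRNA count column.

    Each snoRNA receives exactly ``counts[name]`` forward-strand reads fully
    inside its interval (shorter intervals shorten the read). ``n_background``
    reads are placed uniformly on the chromosome, standing in for other RNA
    species. Returns ``(reads, reference_lengths)``.
    """
    rng = child_rng(seed, f"snorna-reads/{sample_id}")
    chroms = {}
    for chrom, grp in annotation.groupby("chrom"):
        chroms[str(chrom)] = int(chrom_length or max(grp["end"].max() + 1000, 5000))
    reads: list[ReadTuple] = []
    k = 0
    for row in annotation.itertuples(index=False):
        n = int(counts.get(row.name, 0))
        length = min(read_length, row.end - row.start)
        for _ in range(n):
            start0 = int(rng.integers(row.start, row.end - length + 1))
            reads.append((str(row.chrom), start0 + 1, start0 + length, f"{sample_id}:r{k}"))
            k += 1
    intervals = {
        chrom: [(int(r.start), int(r.end)) for r in grp.itertuples(index=False)]
        for chrom, grp in annotation.groupby("chrom")
    }
    for _ in range(int(n_background)):
        # background stands for other RNA species: placed clear of snoRNA loci
        while True:
            chrom = str(rng.choice(list(chroms)))
            start0 = int(rng.integers(0, chroms[chrom] - read_length))
            if all(start0 + read_length <= s or start0 >= e
                   for s, e in intervals.get(chrom, [])):
                break
        reads.append((chrom, start0 + 1, start0 + read_length, f"{sample_id}:bg{k}"))
        k += 1
    return io.sort_reads(reads), chroms


# ---------------------------------------------------------------------------
# Pooled CRISPR screen counts
# ---------------------------------------------------------------------------

NONTARGETING = "nontargeting"


@dataclass(frozen=True)
class TargetSpec:
    """One screened target: its gRNA count and fitness effect per doubling."""

    target: str
    n_grnas: int
    fitness: float = 0.0  # s per doubling; negative = depleted over time


@dataclass
class SimScreenConfig:
    """Parameters of the pooled-screen count generator.

    Timepoints default to the day-0 baseline plus selections at days 3, 5
    and 9 post-transduction, two independent replicates, and a growth model
    in which a gRNA's clone doubles ``doublings_per_day × day`` times with
    per-doubling relative fitness ``1 + s``.
    """

    targets: list[TargetSpec] = field(default_factory=list)
    n_nontargeting: int = 50
    timepoints_days: tuple[int, ...] = (0, 3, 5, 9)
    doublings_per_day: float = 1.0
    replicates: int = 2
    depth: int = 1_000_000
    grna_abundance_log_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.depth <= 0:
            errors.append("depth must be > 0")
        if len(self.timepoints_days) < 2 or 0 not in self.timepoints_days:
            errors.append("need >= 2 timepoints including day 0")
        for t in self.targets:
            if not 2 <= t.n_grnas <= 6:
                errors.append(f"target {t.target}: n_grnas must be in 2..6")
            if abs(t.fitness) >= 1:
                errors.append(f"target {t.target}: |fitness| >= 1 (growth model undefined)")
        if self.n_nontargeting < 0:
            errors.append("n_nontargeting must be >= 0")
        if errors:
            raise ValueError("invalid SimScreenConfig: " + "; ".join(errors))


def screen_sample_name(day: int, replicate: int) -> str:
    return f"d{day}_r{replicate}"


def simulate_screen_counts(config: SimScreenConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate gRNA counts over the screen time course.

    Returns ``(table, truth)`` where ``table`` has columns
    ``grna, target, d{day}_r{rep}…`` and ``truth`` maps targets to their
    fitness. Counts per sample are one multinomial draw of ``depth`` reads
    from the relative clone abundances at that day, so per-sample totals
    equal the configured depth exactly; replicates share true fitness and
    initial library composition but are independent draws.
    """
    rng = child_rng(config.seed, "screen-counts")
    grnas, targets, fitness = [], [], []
    for spec in config.targets:
        for g in range(1, spec.n_grnas + 1):
            grnas.append(f"{spec.target}_g{g}")
            targets.append(spec.target)
            fitness.append(spec.fitness)
    for g in range(1, config.n_nontargeting + 1):
        grnas.append(f"NT_g{g}")
        targets.append(NONTARGETING)
        fitness.append(0.0)
    fitness_arr = np.array(fitness)
    abundance0 = rng.lognormal(0.0, config.grna_abundance_log_sd, size=len(grnas))
    data = {"grna": grnas, "target": targets}
    for day in config.timepoints_days:
        doublings = config.doublings_per_day * day
        abundance = abundance0 * np.power(1.0 + fitness_arr, doublings)
        probs = abundance / abundance.sum()
        for rep in range(1, config.replicates + 1):
            data[screen_sample_name(day, rep)] = rng.multinomial(config.depth, probs)
    table = pd.DataFrame(data)
    truth = pd.DataFrame(
        {
            "target": [t.target for t in config.targets] + ([NONTARGETING] if config.n_nontargeting else []),
            "fitness": [t.fitness for t in config.targets] + ([0.0] if config.n_nontargeting else []),
            "n_grnas": [t.n_grnas for t in config.targets]
            + ([config.n_nontargeting] if config.n_nontargeting else []),
        }
    )
    return table, truth
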