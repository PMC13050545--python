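"""Seeded synthetic-data generators for the multiome fate pipeline.

Every input the pipeline consumes can be produced here with planted ground
truth: a somatic-mutation cohort with subgroup and hotspot structure, a
three-lineage (basal / L1 / L2) multiome with signature-gene expression
shifts and motif-planted accessible peaks, per-cell QC fixtures with exact
violation bookkeeping, and an enhancer-truth system where known tiles drive
a target gene's expression.

All generators are pure functions of their arguments including the seed:
identical configuration gives byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

LINEAGES = ("basal", "L1", "L2")

#: Lineage-characteristic motif analogues as 4xW column-stochastic matrices
#: (rows A, C, G, T).  These are synthetic stand-ins built from field-typical
#: consensus sequences -- an ARE half-site + FOXA1 composite, a canonical
#: inverted-repeat ARE, a POU-family octamer, a GATA zinc-finger site and a
#: p53-family half-site -- not matrices exported from any motif database.
MOTIF_CONSENSUS = {
    "ARE_FOXA1_hybrid": "TGTTCTTGTTTAC",
    "ARE_canonical": "AGAACANNNTGTTCT",
    "POU2F1_like": "ATGCAAAT",
    "GATA3_like": "AGATAAGA",
    "TRP63_like": "GGGCATGTCC",
}

#: Which motif is planted in which lineage's specific peaks by default.
LINEAGE_MOTIFS = {
    "L1": ("ARE_FOXA1_hybrid", "POU2F1_like", "GATA3_like"),
    "L2": ("ARE_canonical",),
    "basal": ("TRP63_like",),
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = np.array(list("ACGT"))


def consensus_to_pfm(consensus: str, dominant: float = 0.88) -> np.ndarray:
    """Turn a consensus string (with N for uniform columns) into a 4xW PFM."""
    w = len(consensus)
    pfm = np.full((4, w), (1.0 - dominant) / 3.0)
    for j, base in enumerate(consensus.upper()):
        if base == "N":
            pfm[:, j] = 0.25
        else:
            pfm[:, j] = (1.0 - dominant) / 3.0
            pfm[_BASE_INDEX[base], j] = dominant
    return pfm


def builtin_motif_pfms() -> dict[str, np.ndarray]:
    """The built-in synthetic motif set as {id: 4xW probability matrix}."""
    return {name: consensus_to_pfm(cons) for name, cons in MOTIF_CONSENSUS.items()}


# ---------------------------------------------------------------------------
# configuration / truth containers
# ---------------------------------------------------------------------------


def _default_cells() -> dict[str, int]:
    # 6 / 28 / 66 percent of 3000 cells -- echoes the lineage mix of a
    # truncation-mutant organoid culture dominated by L1 cells.
    return {"basal": 180, "L2": 840, "L1": 1980}


def _default_plant_rates() -> dict[tuple[str, str], float]:
    rates: dict[tuple[str, str], float] = {}
    for lineage, motifs in LINEAGE_MOTIFS.items():
        for m in motifs:
            rates[(m, lineage)] = 0.6
    return rates


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic three-lineage multiome.

    ``effect_size`` is the mean log-expression shift of a lineage's
    signature genes in cells of that lineage; ``depth`` is the expected
    RNA library size per cell; ``motif_plant_rate`` maps
    ``(motif_id, lineage)`` to the fraction of that lineage's specific
    peaks carrying a planted instance.
    """

    seed: int = 0
    n_cells_per_lineage: dict[str, int] = field(default_factory=_default_cells)
    n_genes: int = 2000
    n_peaks: int = 1200
    signature_size: int = 30
    effect_size: float = 1.0
    depth: float = 5000.0
    motif_plant_rate: dict[tuple[str, str], float] = field(
        default_factory=_default_plant_rates
    )
    background_gc: float = 0.42
    rna_dispersion: float = 0.3
    peak_length: int = 501

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_cells_per_lineage.values()):
            raise ValueError("cell counts must be non-negative")
        if min(self.n_genes, self.n_peaks, self.signature_size) < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 < self.background_gc < 1.0:
            raise ValueError("background_gc must lie in (0, 1)")
        for key, rate in self.motif_plant_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"plant rate for {key} must lie in [0, 1]")
        if self.signature_size * 3 > self.n_genes:
            raise ValueError(
                "signature_size x 3 exceeds n_genes; signatures must be disjoint"
            )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["motif_plant_rate"] = {f"{m}|{l}": r for (m, l), r in self.motif_plant_rate.items()}
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class TruthBundle:
    """Planted ground truth accompanying a synthetic dataset."""

    lineage_labels: np.ndarray | None = None
    signatures: dict[str, list[str]] = field(default_factory=dict)
    lineage_peaks: dict[str, list[str]] = field(default_factory=dict)
    planted_motif_sites: list[tuple[str, str, int, str]] = field(default_factory=list)
    causal_tiles: dict[int, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# mutation cohort
# ---------------------------------------------------------------------------

_DEFAULT_SUBGROUP_WEIGHTS = {
    "missense": 339 / 991,
    "inframe_indel": 335 / 991,
    "nonsense": 287 / 991,
    "other": 30 / 991,
}
_DEFAULT_HOTSPOTS = {253: 0.5, 254: 0.45, 255: 0.05}

_CLASS_TOKENS = {
    "missense": "Missense_Mutation",
    "inframe_indel": "In_Frame_Del",
    "nonsense": "Nonsense_Mutation",
    "frameshift": "Frame_Shift_Del",
    "other": "Splice_Site",
}

COHORT_COLUMNS = [
    "Patient_ID",
    "Sample_ID",
    "Sample_Type",
    "Variant_Classification",
    "HGVSp_Short",
]

_AA = "ARNDCQEGHILKMFPSTWYV"


def _protein_change(rng: np.random.Generator, subgroup: str, residue: int) -> str:
    aa = _AA[rng.integers(len(_AA))]
    alt = _AA[rng.integers(len(_AA))]
    if subgroup == "missense":
        return f"p.{aa}{residue}{alt}"
    if subgroup == "inframe_indel":
        return f"p.{aa}{residue}del"
    if subgroup == "nonsense":
        return f"p.{aa}{residue}*"
    if subgroup == "frameshift":
        return f"p.{aa}{residue}fs"
    return ""


def _residue_for(rng: np.random.Generator, subgroup: str,
                 hotspots: dict[int, float]) -> int:
    if subgroup == "missense":
        # Wing2-concentrated missense positions
        return int(rng.integers(247, 270))
    if subgroup == "inframe_indel":
        residues = np.array(sorted(hotspots))
        w = np.array([hotspots[r] for r in residues], dtype=float)
        return int(rng.choice(residues, p=w / w.sum()))
    if subgroup in ("nonsense", "frameshift"):
        # C-terminal truncations distal to the Forkhead domain
        return int(rng.integers(270, 473))
    return int(rng.integers(1, 473))


def gen_mutation_cohort(
    n_mutations: int,
    subgroup_weights: dict[str, float] | None = None,
    hotspot_weights: dict[int, float] | None = None,
    met_fraction: float = 305 / 991,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a MAF-like somatic-mutation table with subgroup/hotspot structure.

    Subgroup labels are drawn i.i.d. from ``subgroup_weights``; inframe-indel
    protein positions are drawn from ``hotspot_weights``; each record is a
    metastatic sample with probability ``met_fraction``.
    """
    if n_mutations < 0:
        raise ValueError("n_mutations must be non-negative")
    weights = dict(subgroup_weights or _DEFAULT_SUBGROUP_WEIGHTS)
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("subgroup_weights must sum to 1")
    hotspots = dict(hotspot_weights or _DEFAULT_HOTSPOTS)
    if not 0.0 <= met_fraction <= 1.0:
        raise ValueError("met_fraction must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    subgroups = list(weights)
    probs = np.array([weights[s] for s in subgroups], dtype=float)
    rows = []
    for i in range(n_mutations):
        sub = subgroups[int(rng.choice(len(subgroups), p=probs))]
        residue = _residue_for(rng, sub, hotspots)
        met = rng.random() < met_fraction
        rows.append(
            {
                "Patient_ID": f"P{i:05d}",
                "Sample_ID": f"S{i:05d}",
                "Sample_Type": "metastasis" if met else "primary",
                "Variant_Classification": _CLASS_TOKENS.get(sub, "Unknown"),
                "HGVSp_Short": _protein_change(rng, sub, residue),
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def make_reference_cohort() -> pd.DataFrame:
    """Deterministic synthetic stand-in for the deposited FOXA1 cohort table.

    Realizes exactly the printed cohort marginals: 991 mutations split
    686 primary / 305 metastatic; 339 missense, 335 inframe indels,
    287 nonsense and 30 frameshift/other; 906 distinct cases from 874
    distinct patients (some patients contribute two samples, some samples
    carry two mutations).  This is a synthetic reconstruction matching the
    published summary counts, not the deposited per-patient data.
    """
    rng = np.random.default_rng(991)
    counts = {"missense": 339, "inframe_indel": 335, "nonsense": 287,
              "frameshift": 20, "other": 10}
    subgroups = [s for s, c in counts.items() for _ in range(c)]
    rows = []
    for sub in subgroups:
        residue = _residue_for(rng, sub, _DEFAULT_HOTSPOTS)
        rows.append(
            {
                "Variant_Classification": _CLASS_TOKENS[sub],
                "HGVSp_Short": _protein_change(rng, sub, residue),
            }
        )
    df = pd.DataFrame(rows)
    # interleave subgroups so each occurs at both tumor sites
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    # 991 mutations over 906 cases: the first 85 cases carry two mutations.
    case_idx = np.concatenate([np.repeat(np.arange(85), 2), np.arange(85, 906)])
    # 906 cases over 874 patients: the first 32 patients contribute two cases.
    patient_of_case = np.concatenate(
        [np.repeat(np.arange(32), 2), np.arange(32, 874)]
    )
    df["Sample_ID"] = [f"S{c:04d}" for c in case_idx]
    df["Patient_ID"] = [f"P{patient_of_case[c]:04d}" for c in case_idx]
    # per-case site labels, consistent within a case: the last 305 cases are
    # all singletons (only cases 0-84 are doubled), so marking them
    # metastatic yields exactly 686 primary / 305 metastatic records.
    site_of_case = np.array(["primary"] * 906, dtype=object)
    site_of_case[906 - 305:] = "metastasis"
    df["Sample_Type"] = site_of_case[case_idx]
    return df[COHORT_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# multiome generator
# ---------------------------------------------------------------------------


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def _random_sequences(rng: np.random.Generator, n: int, length: int,
                      gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=(n, length), p=p)


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def gen_multiome(cfg: SimConfig):
    """Generate an RNA count matrix, ATAC count matrix, peak sequences and truth.

    Returns ``(rna, atac, peak_seqs, truth)`` where ``rna`` and ``atac`` are
    :class:`anndata.AnnData` (cells x genes, cells x peaks) with integer
    counts, ``peak_seqs`` maps peak id to an upper-case DNA string, and
    ``truth`` records lineage labels, signatures, lineage-specific peaks and
    planted motif sites.
    """
    import anndata as ad

    rng = np.random.default_rng(cfg.seed)
    lineage_order = [l for l in LINEAGES if l in cfg.n_cells_per_lineage]
    labels = np.concatenate(
        [np.repeat(l, cfg.n_cells_per_lineage[l]) for l in lineage_order]
    )
    n_cells = labels.size
    n_mito = min(10, cfg.n_genes // 20)
    gene_names = [f"mt-g{i + 1}" for i in range(n_mito)] + [
        f"gene{i + 1:05d}" for i in range(cfg.n_genes - n_mito)
    ]

    # disjoint signatures drawn from the non-mito genes
    non_mito = gene_names[n_mito:]
    signatures = {}
    for k, lineage in enumerate(LINEAGES):
        lo = k * cfg.signature_size
        signatures[lineage] = list(non_mito[lo:lo + cfg.signature_size])

    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    base /= base.sum()
    name_to_col = {g: j for j, g in enumerate(gene_names)}

    rna_blocks = []
    for lineage in lineage_order:
        nl = cfg.n_cells_per_lineage[lineage]
        mu_g = base.copy()
        for sig_lineage, genes in signatures.items():
            cols = [name_to_col[g] for g in genes]
            shift = cfg.effect_size if sig_lineage == lineage else 0.0
            mu_g[cols] = mu_g[cols] * np.exp(shift)
        mu = cfg.depth * np.broadcast_to(mu_g, (nl, cfg.n_genes))
        rna_blocks.append(_nb_counts(rng, mu, cfg.rna_dispersion))
    rna_counts = np.vstack(rna_blocks) if rna_blocks else np.zeros((0, cfg.n_genes), int)

    # peaks: one quarter specific per lineage, remainder shared
    peak_names = [f"peak{i + 1:05d}" for i in range(cfg.n_peaks)]
    n_spec = cfg.n_peaks // 4
    lineage_peaks = {}
    for k, lineage in enumerate(LINEAGES):
        lineage_peaks[lineage] = peak_names[k * n_spec:(k + 1) * n_spec]
    peak_lineage = np.array(["shared"] * cfg.n_peaks, dtype=object)
    for lineage, names in lineage_peaks.items():
        for name in names:
            peak_lineage[int(name[4:]) - 1] = lineage

    open_prob = np.empty((len(lineage_order), cfg.n_peaks))
    for i, cell_lineage in enumerate(lineage_order):
        q = np.where(peak_lineage == "shared", 0.30, 0.05)
        q = np.where(peak_lineage == cell_lineage, 0.55, q)
        open_prob[i] = q
    atac_blocks = []
    for i, lineage in enumerate(lineage_order):
        nl = cfg.n_cells_per_lineage[lineage]
        opened = rng.random((nl, cfg.n_peaks)) < open_prob[i]
        atac_blocks.append(opened * (1 + rng.poisson(0.8, size=(nl, cfg.n_peaks))))
    atac_counts = np.vstack(atac_blocks) if atac_blocks else np.zeros((0, cfg.n_peaks), int)

    # peak sequences with planted motif instances
    seq_codes = _random_sequences(rng, cfg.n_peaks, cfg.peak_length, cfg.background_gc)
    pfms = builtin_motif_pfms()
    planted: list[tuple[str, str, int, str]] = []
    for (motif_id, lineage), rate in sorted(cfg.motif_plant_rate.items()):
        if rate == 0 or motif_id not in pfms:
            continue
        pfm = pfms[motif_id]
        w = pfm.shape[1]
        target_peaks = lineage_peaks.get(lineage, [])
        for pname in target_peaks:
            if rng.random() >= rate:
                continue
            idx = int(pname[4:]) - 1
            offset = int(rng.integers(0, cfg.peak_length - w + 1))
            inst = np.array([rng.choice(4, p=pfm[:, j]) for j in range(w)])
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                inst = _revcomp_codes(inst)
            seq_codes[idx, offset:offset + w] = inst
            planted.append((pname, motif_id, offset, strand))

    peak_seqs = {
        name: "".join(_BASES[seq_codes[i]]) for i, name in enumerate(peak_names)
    }
    truth = TruthBundle(
        lineage_labels=labels,
        signatures=signatures,
        lineage_peaks=lineage_peaks,
        planted_motif_sites=planted,
    )
    cell_ids = [f"cell{i + 1:05d}" for i in range(n_cells)]
    rna = ad.AnnData(
        X=sparse.csr_matrix(rna_counts),
        obs=pd.DataFrame({"lineage": labels}, index=cell_ids),
        var=pd.DataFrame(index=gene_names),
    )
    atac = ad.AnnData(
        X=sparse.csr_matrix(atac_counts),
        obs=pd.DataFrame({"lineage": labels}, index=cell_ids),
        var=pd.DataFrame({"lineage": peak_lineage}, index=peak_names),
    )
    return rna, atac, peak_seqs, truth


# ---------------------------------------------------------------------------
# QC fixture
# ---------------------------------------------------------------------------


def gen_qc_fixture(
    n_pass: int,
    n_low_count: int,
    n_multiplet: int,
    n_high_mito: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell QC table with exactly the stated number of rule violations.

    Violation classes are disjoint by construction: each failing cell
    violates exactly one RNA filter rule and every passing cell sits safely
    inside all thresholds (ATAC metrics always pass), so expected filter
    counts are exact.
    """
    for name, n in [("n_pass", n_pass), ("n_low_count", n_low_count),
                    ("n_multiplet", n_multiplet), ("n_high_mito", n_high_mito)]:
        if n < 0:
            raise ValueError(f"{name} must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []

    def add(kind: str, total: int, mito: float) -> None:
        rows.append(
            {
                "cell_id": f"{kind}{len(rows):05d}",
                "total_transcripts": int(total),
                "mito_fraction": float(mito),
                "tss_enrichment": float(rng.uniform(6, 12)),
                "n_unique_fragments": int(rng.integers(5000, 50000)),
                "total_reads": int(rng.integers(10_000, 100_000)),
            }
        )

    for _ in range(n_pass):
        add("pass", rng.integers(1000, 50_000), rng.uniform(0.0, 0.2))
    for _ in range(n_low_count):
        add("lowc", rng.integers(0, 500), rng.uniform(0.0, 0.2))
    for _ in range(n_multiplet):
        add("mult", rng.integers(100_001, 300_000), rng.uniform(0.0, 0.2))
    for _ in range(n_high_mito):
        add("mito", rng.integers(1000, 50_000), rng.uniform(0.41, 0.9))
    cols = ["cell_id", "total_transcripts", "mito_fraction",
            "tss_enrichment", "n_unique_fragments", "total_reads"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# enhancer truth
# ---------------------------------------------------------------------------


def gen_enhancer_truth(
    n_cells: int,
    n_tiles: int,
    causal_tiles: set[int] | dict[int, float] | None,
    betas: dict[int, float] | float | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    intercept: float = -7.0,
    open_rate: float = 0.2,
    active_fraction: float = 0.5,
    active_open_rate: float | None = None,
):
    """Sparse tile accessibility plus Poisson expression driven by causal tiles.

    Expression counts are Poisson with
    ``log rate = log(depth) + intercept + sum_t beta_t * acc_t + N(0, noise_sd)``
    so that the fitted model's log-depth offset convention matches the
    generative one.  Returns ``(acc, expr, depth, truth)``.

    When ``active_open_rate`` is given, the first ``active_fraction`` of the
    cells form an "active" state in which causal tiles open at that rate
    while the remaining cells open them at ``open_rate / 4`` -- the
    state-biased enhancer accessibility that per-state Shapley means detect.
    State labels are recorded in ``truth.lineage_labels``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    coef = {}
    if causal_tiles:
        if isinstance(causal_tiles, dict):
            coef = {int(t): float(b) for t, b in causal_tiles.items()}
        else:
            if betas is None:
                raise ValueError("betas required when causal_tiles is a set")
            if np.isscalar(betas):
                coef = {int(t): float(betas) for t in causal_tiles}
            else:
                coef = {int(t): float(betas[t]) for t in causal_tiles}
    if any(not 0 <= t < n_tiles for t in coef):
        raise ValueError("causal tile indices must lie in [0, n_tiles)")

    rng = np.random.default_rng(seed)
    open_p = np.full((n_cells, n_tiles), open_rate)
    n_active = int(round(active_fraction * n_cells))
    labels = np.array(["active"] * n_active + ["inactive"] * (n_cells - n_active))
    if active_open_rate is not None and coef:
        causal_idx = sorted(coef)
        open_p[:n_active, causal_idx] = active_open_rate
        open_p[n_active:, causal_idx] = open_rate / 4.0
    opened = rng.random((n_cells, n_tiles)) < open_p
    acc = opened * (1 + rng.poisson(0.4, size=(n_cells, n_tiles)))
    acc = acc.astype(float)
    depth = rng.lognormal(mean=np.log(5000.0), sigma=0.25, size=n_cells)
    eta = np.log(depth) + intercept + rng.normal(0.0, noise_sd, size=n_cells)
    for t, b in coef.items():
        eta = eta + b * acc[:, t]
    expr = rng.poisson(np.exp(np.clip(eta, -30, 30)))
    truth = TruthBundle(causal_tiles=coef, lineage_labels=labels)
    return acc, expr, depth, truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_mtx_bundle(outdir: str | Path, adata, prefix: str = "") -> None:
    """Write an AnnData as Matrix Market + barcodes.tsv + features.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sparse.csr_matrix(adata.X)
    spio.mmwrite(str(outdir / f"{prefix}matrix.mtx"), X)
    pd.Series(adata.obs_names).to_csv(
        outdir / f"{prefix}barcodes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.var_names).to_csv(
        outdir / f"{prefix}features.tsv", sep="\t", index=False, header=False
    )


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_config_sidecar(path: str | Path, cfg: SimConfig) -> None:
    Path(path).write_text(cfg.to_json())
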