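"""Synthetic developing-limb scRNA-seq counts with known ground truth.

The generator emulates the cellular structure of a whole-limb dissociation:
distinct connective-tissue (CT) and muscle (M) populations, unrelated "other"
populations (vessel/nerve/ectoderm-like), a small *transitional* population
whose CT marker expression declines while muscle marker expression rises along
a latent pseudotime, and barcode doublets formed by summing two singlet
profiles.  Counts are negative-binomial with log-normal library sizes, which
gives realistic over-dispersion and dropout.  Every emitted barcode carries a
ground-truth record, so downstream QC, doublet removal and identity calling
can be scored against the planted structure.

The transitional trajectory is parameterised by two logistic switches in
pseudotime (steepness 10): one turning muscle markers and the muscle gene
program on, one turning CT markers and the CT program off.  In ``late`` mode
pseudotime spans the full trajectory and both switches are traversed; in
``early`` mode pseudotime is confined to the start of the trajectory, where
muscle markers are already rising but CT markers have not yet begun to fall.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

CT_MARKERS: tuple[str, ...] = ("PRRX1", "TWIST2", "PDGFRA", "OSR1", "SCX")
M_MARKERS: tuple[str, ...] = ("PAX7", "MYF5", "MYOD1", "MYOG")
ID_GENES: tuple[str, ...] = ("ID1", "ID2", "ID3")

MITO_PREFIX = "MT-"
TRANSITIONAL = "TRANSITIONAL"
DOUBLET = "DOUBLET"

#: truth table columns written to / read from truth.tsv
TRUTH_COLUMNS = ("population", "pseudotime", "is_doublet", "parent1", "parent2", "high_mito")


class SimConfigError(ValueError):
    """Invalid simulator configuration."""


class DatasetFormatError(ValueError):
    """Malformed on-disk dataset (MTX / TSV tables)."""


def _default_populations() -> dict[str, int]:
    return {"CT": 1500, "M": 1500, "OTHER_1": 700, "OTHER_2": 650, "OTHER_3": 650}


def _default_marker_means() -> dict[str, dict[str, float]]:
    return {
        "CT": {g: 0.005 for g in CT_MARKERS},
        "M": {g: 0.005 for g in M_MARKERS},
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic limb dataset.

    Rates are expressed as expected counts per unit of library size: a gene
    with rate r in a cell with library size L has NB-distributed counts with
    mean ``L * r``.
    """

    n_cells_per_population: Mapping[str, int] = field(default_factory=_default_populations)
    n_genes_total: int = 600
    marker_means: Mapping[str, Mapping[str, float]] = field(default_factory=_default_marker_means)
    dual_fraction: float = 0.04
    doublet_rate: float = 0.05
    biphasic_mode: str = "late"
    nb_dispersion: float = 2.0
    libsize_mu: float = math.log(5000.0)
    libsize_sigma: float = 0.35
    mito_gene_count: int = 20
    mito_high_fraction: float = 0.05
    seed: int = 0

    # gene-panel plumbing (defaults chosen once; see docs/methods.md)
    program_genes_per_population: int = 50
    program_rate: float = 0.012
    housekeeping_rate: float = 0.002  # geometric centre of a two-decade abundance grid
    id_base_rate: float = 0.0005
    id_dual_rate: float = 0.004
    mito_rate: float = 0.0025
    mito_high_factor: float = 16.0
    switch_steepness: float = 10.0

    def validate(self) -> None:
        if not self.n_cells_per_population:
            raise SimConfigError("n_cells_per_population is empty")
        for pop, n in self.n_cells_per_population.items():
            if int(n) < 0:
                raise SimConfigError(f"negative cell count for population {pop!r}")
        if sum(int(n) for n in self.n_cells_per_population.values()) <= 0:
            raise SimConfigError("total singlet count must be positive")
        for name in ("dual_fraction", "doublet_rate", "mito_high_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not np.isfinite(v):
                raise SimConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.doublet_rate >= 1.0:
            raise SimConfigError("doublet_rate must be < 1")
        if self.biphasic_mode not in ("early", "late"):
            raise SimConfigError(f"biphasic_mode must be 'early' or 'late', got {self.biphasic_mode!r}")
        if not (self.nb_dispersion > 0 and np.isfinite(self.nb_dispersion)):
            raise SimConfigError("nb_dispersion must be a positive finite number")
        if self.libsize_sigma < 0:
            raise SimConfigError("libsize_sigma must be >= 0")
        if self.dual_fraction > 0 and not (
            "CT" in self.n_cells_per_population and "M" in self.n_cells_per_population
        ):
            raise SimConfigError("dual_fraction > 0 requires both a CT and an M population")
        for pop, means in self.marker_means.items():
            for gene, rate in means.items():
                if not np.isfinite(rate) or rate < 0:
                    raise SimConfigError(f"invalid rate {rate} for {gene!r} in population {pop!r}")
        if self.dual_fraction > 0:
            for pop, panel in (("CT", CT_MARKERS), ("M", M_MARKERS)):
                missing = [g for g in panel if g not in self.marker_means.get(pop, {})]
                if missing:
                    raise SimConfigError(f"marker_means[{pop!r}] missing panel genes: {missing}")
        n_fixed = (
            len(CT_MARKERS)
            + len(M_MARKERS)
            + len(ID_GENES)
            + self.program_genes_per_population * len(self.n_cells_per_population)
            + self.mito_gene_count
        )
        if self.n_genes_total < n_fixed + 1:
            raise SimConfigError(
                f"n_genes_total={self.n_genes_total} too small: need at least {n_fixed + 1} "
                "(markers + ID + programs + mito + >=1 housekeeping gene)"
            )


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _switch_midpoints(mode: str) -> tuple[float, float]:
    """(muscle-up midpoint, CT-down midpoint) in pseudotime."""
    if mode == "early":
        return 0.10, 0.90
    return 0.20, 0.55


def _pseudotime_upper(mode: str) -> float:
    return 0.5 if mode == "early" else 1.0


def build_gene_table(config: SimConfig) -> pd.DataFrame:
    """Gene ids and roles for the simulated panel, in emission order."""
    pops = list(config.n_cells_per_population)
    genes: list[str] = []
    roles: list[str] = []
    for g in CT_MARKERS:
        genes.append(g)
        roles.append("ct_marker")
    for g in M_MARKERS:
        genes.append(g)
        roles.append("m_marker")
    for g in ID_GENES:
        genes.append(g)
        roles.append("id_gene")
    for pop in pops:
        for i in range(config.program_genes_per_population):
            genes.append(f"PROG-{pop}-{i:03d}")
            roles.append(f"program_{pop}")
    for i in range(config.mito_gene_count):
        genes.append(f"{MITO_PREFIX}{i:02d}")
        roles.append("mito")
    n_hk = config.n_genes_total - len(genes)
    for i in range(n_hk):
        genes.append(f"HK-{i:03d}")
        roles.append("housekeeping")
    return pd.DataFrame({"role": roles}, index=pd.Index(genes, name="gene_id"))


def _log_spread(center: float, n: int, factor: float) -> np.ndarray:
    """Log-spaced grid of n rates spanning center/factor .. center*factor."""
    if n == 1:
        return np.array([center])
    return np.geomspace(center / factor, center * factor, n)


def _housekeeping_rates(config: SimConfig, n_hk: int) -> np.ndarray:
    """Log-spaced abundance grid spanning two decades around the housekeeping
    rate, emulating the abundance continuum of a real transcriptome (so every
    mean-expression bin holds neutral genes, not only population programs)."""
    return _log_spread(config.housekeeping_rate, n_hk, 10.0)


def _rate_table(config: SimConfig, gene_table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-population expression rate vectors (counts per unit library)."""
    roles = gene_table["role"].to_numpy()
    genes = gene_table.index.to_numpy()
    n = len(genes)

    shared = np.zeros(n)
    shared[roles == "housekeeping"] = _housekeeping_rates(config, int((roles == "housekeeping").sum()))
    shared[roles == "mito"] = config.mito_rate
    shared[roles == "id_gene"] = config.id_base_rate

    rates: dict[str, np.ndarray] = {}
    for pop in config.n_cells_per_population:
        r = shared.copy()
        n_prog = int((roles == f"program_{pop}").sum())
        if n_prog:
            # program genes span a range of abundances (like real structural
            # genes), so they interleave with housekeeping genes in
            # mean-expression bins instead of forming program-only bins
            r[roles == f"program_{pop}"] = _log_spread(config.program_rate, n_prog, 3.0)
        for gene, rate in config.marker_means.get(pop, {}).items():
            idx = np.flatnonzero(genes == gene)
            if idx.size == 0:
                raise SimConfigError(f"marker_means references unknown gene {gene!r}")
            r[idx[0]] = rate
        rates[pop] = r
    return rates


def _transitional_rates(
    config: SimConfig, gene_table: pd.DataFrame, rates: dict[str, np.ndarray], pseudotime: np.ndarray
) -> np.ndarray:
    """cells x genes rate matrix for transitional cells at the given pseudotimes."""
    roles = gene_table["role"].to_numpy()
    shared = np.zeros(len(gene_table))
    shared[roles == "housekeeping"] = _housekeeping_rates(config, int((roles == "housekeeping").sum()))
    shared[roles == "mito"] = config.mito_rate
    shared[roles == "id_gene"] = config.id_dual_rate  # planted BMP-readout signal

    def _specific(pop: str, role_names: list[str]) -> np.ndarray:
        spec = rates[pop].copy()
        spec[~np.isin(roles, role_names)] = 0.0
        return spec

    ct_markers = _specific("CT", ["ct_marker"])
    m_markers = _specific("M", ["m_marker"])
    ct_program = _specific("CT", ["program_CT"])
    m_program = _specific("M", ["program_M"])

    # marker TFs lead, transcriptional programs follow: muscle markers rise at
    # the early switch; CT markers decline and the CT program hands over to the
    # muscle program at the late switch (the swap conserves library composition)
    t_m, t_ct = _switch_midpoints(config.biphasic_mode)
    s = config.switch_steepness
    m_mark_mult = _sigmoid(s * (pseudotime - t_m))[:, None]
    late = _sigmoid(s * (pseudotime - t_ct))[:, None]
    return (
        shared[None, :]
        + (1.0 - late) * ct_markers[None, :]
        + m_mark_mult * m_markers[None, :]
        + (1.0 - late) * ct_program[None, :]
        + late * m_program[None, :]
    )


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, size=dispersion) draws; mean 0 yields 0 exactly."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(np.int64)


def simulate_counts(config: SimConfig) -> ad.AnnData:
    """Simulate the full dataset (singlets, transitional cells, doublets).

    Returns an AnnData with raw counts in ``X`` (cells x genes, CSR),
    ground-truth per-cell labels in ``obs`` and gene roles in ``var``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    s_counts, s_doublet = ss.spawn(2)
    rng = np.random.default_rng(s_counts)

    gene_table = build_gene_table(config)
    rates = _rate_table(config, gene_table)

    pops = list(config.n_cells_per_population)
    n_by_pop = {p: int(config.n_cells_per_population[p]) for p in pops}
    n_base = sum(n_by_pop.values())
    f = config.dual_fraction
    n_trans = int(round(f * n_base / (1.0 - f))) if f > 0 else 0

    populations: list[str] = []
    for p in pops:
        populations += [p] * n_by_pop[p]
    populations += [TRANSITIONAL] * n_trans
    n_singlets = len(populations)

    pseudotime = np.full(n_singlets, np.nan)
    if n_trans:
        upper = _pseudotime_upper(config.biphasic_mode)
        pseudotime[n_base:] = rng.uniform(0.0, upper, size=n_trans)

    libsize = rng.lognormal(config.libsize_mu, config.libsize_sigma, size=n_singlets)

    mean = np.empty((n_singlets, len(gene_table)))
    row = 0
    for p in pops:
        k = n_by_pop[p]
        mean[row : row + k] = rates[p][None, :]
        row += k
    if n_trans:
        mean[n_base:] = _transitional_rates(config, gene_table, rates, pseudotime[n_base:])
    mean *= libsize[:, None]

    n_high = int(round(config.mito_high_fraction * n_singlets))
    high_mito = np.zeros(n_singlets, dtype=bool)
    if n_high:
        high_mito[rng.choice(n_singlets, size=n_high, replace=False)] = True
        mito_cols = gene_table["role"].to_numpy() == "mito"
        mean[np.ix_(high_mito, mito_cols)] *= config.mito_high_factor

    counts = _draw_counts(rng, mean, config.nb_dispersion)

    obs = pd.DataFrame(
        {
            "population": populations,
            "pseudotime": pseudotime,
            "is_doublet": np.zeros(n_singlets, dtype=bool),
            "parent1": [""] * n_singlets,
            "parent2": [""] * n_singlets,
            "high_mito": high_mito,
        },
        index=pd.Index([f"CELL_{i:05d}" for i in range(n_singlets)], name="barcode"),
    )
    adata = ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=gene_table.copy())
    if config.doublet_rate > 0:
        adata = inject_doublets(
            adata, config.doublet_rate, seed=int(s_doublet.generate_state(1)[0] % 2**31)
        )
    adata.uns["sim_config"] = {"seed": config.seed, "biphasic_mode": config.biphasic_mode}
    return adata


def _ensure_truth_columns(obs: pd.DataFrame) -> pd.DataFrame:
    """Fill default ground-truth columns for datasets not built by the
    simulator (e.g. user-provided matrices)."""
    obs = obs.copy()
    defaults = {
        "population": "",
        "pseudotime": np.nan,
        "is_doublet": False,
        "parent1": "",
        "parent2": "",
        "high_mito": False,
    }
    for col, default in defaults.items():
        if col not in obs:
            obs[col] = default
    return obs


def inject_doublets(adata: ad.AnnData, rate: float, seed: int) -> ad.AnnData:
    """Append doublet barcodes whose counts are sums of two distinct singlets.

    The number appended is ``ceil(rate * n_final)`` where
    ``n_final = n_singlets / (1 - rate)``, so the doublets make up ``rate`` of
    the final barcodes (up to rounding).  Parent totals are conserved exactly.
    """
    if not (0.0 <= rate < 1.0):
        raise SimConfigError(f"doublet rate must lie in [0, 1), got {rate}")
    if rate == 0.0:
        return adata
    n = adata.n_obs
    if n < 2:
        raise SimConfigError("need at least 2 singlets to form doublets")
    n_doub = math.ceil(rate * n / (1.0 - rate) - 1e-9)
    rng = np.random.default_rng(seed)
    i1 = rng.integers(0, n, size=n_doub)
    i2 = (i1 + 1 + rng.integers(0, n - 1, size=n_doub)) % n  # distinct by construction

    X = adata.X.tocsr()
    Xd = X[i1] + X[i2]
    barcodes = adata.obs_names.to_numpy()
    obs_d = pd.DataFrame(
        {
            "population": [DOUBLET] * n_doub,
            "pseudotime": np.full(n_doub, np.nan),
            "is_doublet": np.ones(n_doub, dtype=bool),
            "parent1": barcodes[i1],
            "parent2": barcodes[i2],
            "high_mito": np.zeros(n_doub, dtype=bool),
        },
        index=pd.Index([f"CELL_{n + i:05d}" for i in range(n_doub)], name="barcode"),
    )
    out = ad.AnnData(
        X=sparse.vstack([X, Xd]).tocsr(),
        obs=pd.concat([_ensure_truth_columns(adata.obs), obs_d]),
        var=adata.var.copy(),
    )
    out.uns.update(adata.uns)
    return out


# ---------------------------------------------------------------------------
# dataset directory I/O (10x-style triplet + truth table)
# ---------------------------------------------------------------------------

def write_dataset(adata: ad.AnnData, directory: str | os.PathLike) -> None:
    """Write matrix.mtx (genes as rows), features.tsv, barcodes.tsv, truth.tsv."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    X = sparse.coo_matrix(adata.X.T)  # genes x cells on disk
    X = sparse.coo_matrix((np.asarray(X.data, dtype=np.int64), (X.row, X.col)), shape=X.shape)
    scio.mmwrite(os.path.join(directory, "matrix.mtx"), X, field="integer")

    roles = adata.var["role"] if "role" in adata.var else pd.Series("", index=adata.var_names)
    feats = pd.DataFrame({"gene_id": adata.var_names, "gene_name": adata.var_names, "role": roles.to_numpy()})
    feats.to_csv(os.path.join(directory, "features.tsv"), sep="\t", header=False, index=False)
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(adata.obs_names) + "\n")

    truth = _ensure_truth_columns(adata.obs).loc[:, list(TRUTH_COLUMNS)]
    truth["is_doublet"] = truth["is_doublet"].astype(int)
    truth["high_mito"] = truth["high_mito"].astype(int)
    truth.to_csv(
        os.path.join(directory, "truth.tsv"), sep="\t", na_rep="", float_format="%.10g",
        index=True, index_label="barcode",
    )


def _parse_mtx(path: str) -> sparse.coo_matrix:
    with open(path) as fh:
        header = fh.readline()
    tokens = header.strip().split()
    if (
        len(tokens) != 5
        or tokens[0] != "%%MatrixMarket"
        or tokens[1] != "matrix"
        or tokens[2] != "coordinate"
    ):
        raise DatasetFormatError(f"{path}: line 1: malformed MatrixMarket header: {header.strip()!r}")
    if tokens[4] != "general":
        raise DatasetFormatError(f"{path}: line 1: only 'general' symmetry is supported")
    field_kind = tokens[3]
    if field_kind not in ("integer", "real"):
        raise DatasetFormatError(f"{path}: line 1: unsupported field {field_kind!r} (counts must be integer)")

    # locate the size line (first non-comment after the header) and its line number
    size_lineno = None
    n_rows = n_cols = n_nnz = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 or line.startswith("%") or not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise DatasetFormatError(f"{path}: line {lineno}: expected 'rows cols nnz' size line")
            try:
                n_rows, n_cols, n_nnz = (int(p) for p in parts)
            except ValueError:
                raise DatasetFormatError(f"{path}: line {lineno}: non-integer size line") from None
            size_lineno = lineno
            break
    if size_lineno is None:
        raise DatasetFormatError(f"{path}: missing size line")

    try:
        body = pd.read_csv(
            path, sep=r"\s+", comment="%", header=None, skiprows=size_lineno, dtype=str,
        )
    except pd.errors.EmptyDataError:
        body = pd.DataFrame(columns=[0, 1, 2])
    if len(body) != n_nnz:
        raise DatasetFormatError(f"{path}: declared {n_nnz} entries, found {len(body)}")
    if n_nnz and body.shape[1] != 3:
        raise DatasetFormatError(f"{path}: entries must have 3 fields (row col value)")

    def _as_int(col: pd.Series, what: str) -> np.ndarray:
        vals = pd.to_numeric(col, errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            # entry lines start right after the size line
            lineno = size_lineno + 1 + int(np.flatnonzero(bad.to_numpy())[0])
            raise DatasetFormatError(f"{path}: line {lineno}: non-integer {what} {col[bad.idxmax()]!r}")
        return vals.to_numpy().astype(np.int64)

    if n_nnz:
        rows = _as_int(body[0], "row index")
        cols = _as_int(body[1], "column index")
        data = _as_int(body[2], "entry")
        if (rows < 1).any() or (rows > n_rows).any() or (cols < 1).any() or (cols > n_cols).any():
            bad = ((rows < 1) | (rows > n_rows) | (cols < 1) | (cols > n_cols)).argmax()
            raise DatasetFormatError(
                f"{path}: line {size_lineno + 1 + int(bad)}: index out of declared bounds"
            )
        rows, cols = rows - 1, cols - 1  # 1-based on disk, 0-based in memory
    else:
        rows = cols = data = np.empty(0, dtype=np.int64)
    return sparse.coo_matrix((data, (rows, cols)), shape=(n_rows, n_cols))


def read_dataset(directory: str | os.PathLike) -> ad.AnnData:
    """Read a dataset directory written by :func:`write_dataset`."""
    directory = os.fspath(directory)
    mtx = _parse_mtx(os.path.join(directory, "matrix.mtx"))

    fpath = os.path.join(directory, "features.tsv")
    feats = pd.read_csv(fpath, sep="\t", header=None, dtype=str)
    if feats.shape[1] not in (2, 3):
        raise DatasetFormatError(f"{fpath}: expected 2 or 3 columns, found {feats.shape[1]}")
    gene_ids = feats[0].to_numpy()
    if len(set(gene_ids)) != len(gene_ids):
        raise DatasetFormatError(f"{fpath}: duplicate gene ids")
    # MYOD is accepted as an alias of the canonical chicken symbol MYOD1
    gene_ids = np.where(gene_ids == "MYOD", "MYOD1", gene_ids)

    bpath = os.path.join(directory, "barcodes.tsv")
    with open(bpath) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if len(set(barcodes)) != len(barcodes):
        raise DatasetFormatError(f"{bpath}: duplicate barcodes")

    if mtx.shape[0] != len(gene_ids):
        raise DatasetFormatError(
            f"matrix declares {mtx.shape[0]} genes but features.tsv has {len(gene_ids)} rows"
        )
    if mtx.shape[1] != len(barcodes):
        raise DatasetFormatError(
            f"matrix declares {mtx.shape[1]} cells but barcodes.tsv has {len(barcodes)} rows"
        )
    if mtx.nnz and (np.asarray(mtx.data) < 0).any():
        raise DatasetFormatError("matrix.mtx: negative counts")

    var = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    var["role"] = feats[2].to_numpy() if feats.shape[1] == 3 else ""

    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    tpath = os.path.join(directory, "truth.tsv")
    if os.path.exists(tpath):
        truth = pd.read_csv(
            tpath, sep="\t", index_col="barcode",
            dtype={"parent1": str, "parent2": str, "population": str},
        )
        if set(truth.index) != set(barcodes):
            raise DatasetFormatError(f"{tpath}: barcodes do not match barcodes.tsv")
        truth = truth.loc[barcodes]
        truth["is_doublet"] = truth["is_doublet"].astype(bool)
        truth["high_mito"] = truth["high_mito"].astype(bool)
        for col in ("parent1", "parent2"):
            truth[col] = truth[col].fillna("")
        bad = truth["is_doublet"] & (
            (truth["parent1"] == "") | (truth["parent1"] == truth["parent2"])
        )
        if bad.any():
            raise DatasetFormatError(f"{tpath}: doublet rows need two distinct parents")
        obs = truth

    return ad.AnnData(X=mtx.T.tocsr().astype(np.int64), obs=obs, var=var)


def expected_library_size(config: SimConfig) -> float:
    """E[library size] under the log-normal library model."""
    return math.exp(config.libsize_mu + 0.5 * config.libsize_sigma**2)


def with_overrides(config: SimConfig, **kwargs) -> SimConfig:
    """A copy of *config* with the given fields replaced."""
    return replace(config, **kwargs)
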