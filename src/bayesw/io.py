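"""Readers/writers: PLINK1 binary genotypes, phenotype/covariate/group text
tables, chain output, and run manifests.

The PLINK .bed dialect is SNP-major with magic bytes 0x6C 0x1B 0x01 and
2-bit codes 00 = hom-A1, 01 = missing, 10 = het, 11 = hom-A2; allele counts
are reported for the A1 allele.  Text formats are whitespace-delimited with
'#' comments, chosen for diff-ability.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SurvivalData
from .gibbs import GroupLayout, PosteriorSamples
from .sparse import GenotypeMatrix

__all__ = [
    "read_plink",
    "write_plink",
    "read_phenotype",
    "read_covariates",
    "read_groups",
    "build_maf_ld_groups",
    "RunConfig",
    "write_samples",
    "read_beta_samples",
    "write_manifest",
]

logger = logging.getLogger("bayesw")

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> A1 allele count (-1 = missing)
_CODE_TO_COUNT = np.array([2, -1, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}

_BIM_COLS = ["chrom", "id", "cm", "pos", "a1", "a2"]
_FAM_COLS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


def read_plink(prefix: str | Path,
               drop_invalid: bool = True) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Load a PLINK1 bed/bim/fam triple into a sparse GenotypeMatrix.

    Monomorphic or all-missing markers are dropped with a logged count.
    Returns (genotypes, fam table).
    """
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=_BIM_COLS, comment="#")
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=_FAM_COLS, comment="#")
    n, m = len(fam), len(bim)
    if m == 0:
        raise ValueError("empty marker set in .bim")
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK1 .bed file (magic bytes)")
    bpm = (n + 3) // 4  # bytes per marker
    body = raw[3:]
    if body.size != bpm * m:
        raise ValueError(
            f"truncated .bed: expected {bpm * m} data bytes, got {body.size}")
    codes = body.reshape(m, bpm)
    shifts = np.arange(4, dtype=np.uint8) * 2
    # (m, bpm, 4) -> (m, n): 2-bit fields, little-endian within each byte
    two_bit = (codes[:, :, None] >> shifts[None, None, :]) & 3
    counts = _CODE_TO_COUNT[two_bit.reshape(m, -1)[:, :n]].T  # (n, m)
    keep = np.ones(m, dtype=bool)
    for j in range(m):
        col = counts[:, j]
        called = col[col >= 0]
        if called.size == 0 or called.max() == called.min():
            keep[j] = False
    dropped = int((~keep).sum())
    if dropped:
        if not drop_invalid:
            raise ValueError(f"{dropped} monomorphic/all-missing markers")
        logger.info("dropped %d monomorphic or all-missing markers", dropped)
    if not keep.any():
        raise ValueError("no polymorphic markers left after filtering")
    X = GenotypeMatrix.from_counts(counts[:, keep],
                                   bim.loc[keep].reset_index(drop=True))
    return X, fam


def write_plink(prefix: str | Path, X: GenotypeMatrix,
                fam: pd.DataFrame | None = None) -> None:
    """Write a GenotypeMatrix back to bed/bim/fam (round-trip identity)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = X.n_individuals, X.n_markers
    X.markers[_BIM_COLS].to_csv(prefix.with_suffix(".bim"), sep="\t",
                                header=False, index=False)
    if fam is None:
        fam = pd.DataFrame({
            "fid": [f"F{i + 1}" for i in range(n)],
            "iid": [f"I{i + 1}" for i in range(n)],
            "father": 0, "mother": 0, "sex": 0, "phenotype": -9,
        })
    fam[_FAM_COLS].to_csv(prefix.with_suffix(".fam"), sep="\t",
                          header=False, index=False)
    bpm = (n + 3) // 4
    out = np.zeros((m, bpm), dtype=np.uint8)
    for j in range(m):
        col = X.counts_col(j)
        codes = np.array([_COUNT_TO_CODE[int(c)] for c in col],
                         dtype=np.uint8)
        padded = np.zeros(bpm * 4, dtype=np.uint8)
        padded[:n] = codes
        quads = padded.reshape(bpm, 4)
        out[j] = (quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4)
                  | (quads[:, 3] << 6))
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


def _read_table(path: str | Path, min_cols: int) -> pd.DataFrame:
    """Whitespace table with '#' comments and an optional header line."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, dtype=str)
    if df.shape[1] < min_cols:
        raise ValueError(f"{path}: expected at least {min_cols} columns")
    try:
        float(df.iloc[0, 2])
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)
    return df


def read_phenotype(path: str | Path) -> tuple[SurvivalData, pd.DataFrame]:
    """Phenotype table: FID IID time failure [trunc_age]; header optional.

    Times are in original units and are logged internally.  Returns the
    survival data (without covariates) and the FID/IID table in file order.
    """
    df = _read_table(path, 4)
    ids = df.iloc[:, :2].set_axis(["fid", "iid"], axis=1)
    time = df.iloc[:, 2].astype(float).to_numpy()
    failure = df.iloc[:, 3].astype(float).astype(int).to_numpy()
    trunc = (df.iloc[:, 4].astype(float).to_numpy()
             if df.shape[1] > 4 else None)
    data = SurvivalData.from_times(time, failure, trunc_age=trunc)
    return data, ids


def read_covariates(path: str | Path, ids: pd.DataFrame) -> np.ndarray:
    """Covariate table FID IID c1 c2 ...; z-scored, aligned to ``ids``."""
    df = _read_table(path, 3)
    df = df.set_axis(["fid", "iid"] + [f"c{i}" for i in range(df.shape[1] - 2)],
                     axis=1)
    merged = ids.merge(df, on=["fid", "iid"], how="left", validate="one_to_one")
    vals = merged.iloc[:, 2:].astype(float).to_numpy()
    if np.isnan(vals).any():
        missing = ids[np.isnan(vals).any(axis=1)]
        raise ValueError(
            f"covariates missing for {len(missing)} individuals "
            f"(first: {missing.iloc[0].tolist()})")
    sd = vals.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant covariate column")
    logger.info("covariates z-scored (%d columns)", vals.shape[1])
    return (vals - vals.mean(axis=0)) / sd


def read_groups(path: str | Path, X: GenotypeMatrix, constants: list,
                on_missing: str = "error") -> GroupLayout:
    """Two-column marker_id -> group-label map.

    ``constants`` is one mixture-constant vector per distinct label (sorted
    label order).  Markers absent from the file either raise or are assigned
    to a final catch-all group, per ``on_missing`` ('error' | 'drop' is not
    supported here because the genotype matrix is fixed; use 'extra_group').
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["id", "label"], dtype=str)
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate marker row in group file: {dup}")
    labels = sorted(df["label"].unique())
    label_to_idx = {lab: i for i, lab in enumerate(labels)}
    mapping = dict(zip(df["id"], df["label"]))
    ids = X.ids
    unknown = [i for i in ids if i not in mapping]
    if unknown:
        if on_missing == "error":
            raise ValueError(
                f"{len(unknown)} markers missing from group file "
                f"(first: {unknown[0]})")
        if on_missing != "extra_group":
            raise ValueError("on_missing must be 'error' or 'extra_group'")
        label_to_idx["__ungrouped__"] = len(labels)
    group_of = np.array(
        [label_to_idx[mapping.get(i, "__ungrouped__")] for i in ids],
        dtype=np.int64)
    n_groups = group_of.max() + 1
    if len(constants) == 1:
        constants = list(constants) * n_groups
    if len(constants) != n_groups:
        raise ValueError(
            f"need {n_groups} mixture-constant vectors, got {len(constants)}")
    return GroupLayout(group_of=group_of, constants=constants)


def build_maf_ld_groups(X: GenotypeMatrix, constants,
                        n_maf: int = 5, n_ld: int = 4,
                        ld_window_bp: float = 1e6) -> GroupLayout:
    """MAF-quantile x LD-score-quantile groups computed from the data.

    The LD score of a marker is the sum of r^2 to markers within the window
    (1 Mb default, a rough 1 cM proxy).  Quantile cuts are taken within the
    data, giving n_maf * n_ld groups; sparsely populated cells are merged
    into their MAF quintile's neighbour implicitly by quantile ties.
    """
    maf = X.maf
    pos = X.markers["pos"].to_numpy()
    chrom = X.markers["chrom"].to_numpy()
    m = X.n_markers
    ld = np.zeros(m)
    xs = X.toarray()
    for j in range(m):
        near = np.flatnonzero((chrom == chrom[j])
                              & (np.abs(pos - pos[j]) <= ld_window_bp))
        near = near[near != j]
        if near.size:
            r = xs[:, near].T @ xs[:, j] / X.n_individuals
            ld[j] = float(np.sum(r * r))
    maf_bin = np.minimum(
        np.searchsorted(np.quantile(maf, np.linspace(0, 1, n_maf + 1)[1:-1]),
                        maf, side="right"), n_maf - 1)
    group_of = np.empty(m, dtype=np.int64)
    for b in range(n_maf):
        sel = maf_bin == b
        cuts = np.quantile(ld[sel], np.linspace(0, 1, n_ld + 1)[1:-1])
        ld_bin = np.minimum(np.searchsorted(cuts, ld[sel], side="right"),
                            n_ld - 1)
        group_of[sel] = b * n_ld + ld_bin
    # re-index to the non-empty groups only
    used = np.unique(group_of)
    remap = {g: i for i, g in enumerate(used)}
    group_of = np.array([remap[g] for g in group_of], dtype=np.int64)
    constants = [np.asarray(constants, float)] * used.size
    return GroupLayout(group_of=group_of, constants=constants)


# ---------------------------------------------------------------------------
# Run configuration, chain output, manifests
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved settings for one command-line run."""

    mode: str = "fit"
    bed_prefix: str = ""
    phenotype: str = ""
    covariates: str = ""
    groups: str = ""
    out_dir: str = "bayesw_out"
    mixtures: tuple = (0.00001, 0.0001, 0.001, 0.01)
    quadrature_points: int = 25
    chains: int = 1
    iterations: int = 10_000
    burn_in: int | None = None
    thinning: int = 5
    seed: int = 0
    workers: int = 1
    sync_rate: int = 1
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        mx = np.asarray(self.mixtures, float)
        if np.any(mx <= 0) or np.any(np.diff(mx) <= 0):
            raise ValueError("mixtures must be positive and strictly increasing")
        if self.iterations <= 0 or self.thinning <= 0 or self.chains <= 0:
            raise ValueError("iterations, thinning and chains must be positive")


def write_samples(samples: PosteriorSamples, out_dir: str | Path,
                  prefix: str = "chain") -> dict:
    """Chain output: hyperparameters as CSV, marker effects in long format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"{prefix}{samples.chain_id}"
    hyper = pd.DataFrame({"sample": np.arange(samples.n_samples),
                          "alpha": samples.alpha, "mu": samples.mu})
    for g in range(samples.sigma2_g.shape[1]):
        hyper[f"sigma2_g{g}"] = samples.sigma2_g[:, g]
        for k in range(samples.pi.shape[2]):
            hyper[f"pi{g}_{k}"] = samples.pi[:, g, k]
    for q in range(samples.delta.shape[1]):
        hyper[f"delta{q}"] = samples.delta[:, q]
    hyper_path = out / f"{tag}_hyperparameters.csv"
    hyper.to_csv(hyper_path, index=False)
    betas = pd.DataFrame({
        "sample": samples.beta_sample,
        "marker": samples.beta_marker,
        "mixture": samples.beta_mixture,
        "beta": samples.beta_value,
    })
    beta_path = out / f"{tag}_betas.csv"
    betas.to_csv(beta_path, index=False)
    return {"hyperparameters": str(hyper_path), "betas": str(beta_path)}


def read_beta_samples(path: str | Path, n_markers: int) -> PosteriorSamples:
    """Rebuild a minimal PosteriorSamples (effects only) from a betas CSV."""
    df = pd.read_csv(path)
    n_s = int(df["sample"].max()) + 1 if len(df) else 0
    empty = np.zeros((n_s, 0))
    return PosteriorSamples(
        alpha=np.full(n_s, np.nan), mu=np.full(n_s, np.nan),
        sigma2_g=np.zeros((n_s, 1)), pi=np.zeros((n_s, 1, 1)), delta=empty,
        beta_sample=df["sample"].to_numpy(np.int64),
        beta_marker=df["marker"].to_numpy(np.int64),
        beta_mixture=df["mixture"].to_numpy(np.int64),
        beta_value=df["beta"].to_numpy(float),
        n_markers=n_markers, iterations=0, burn_in=0, thinning=1,
        seed=-1, chain_id=-1)


def write_manifest(cfg: RunConfig, out_dir: str | Path,
                   outputs: dict | None = None) -> Path:
    """Machine-readable record sufficient to reproduce deterministic outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"config": asdict(cfg), "outputs": outputs or {}}
    from . import __version__

    payload["versions"] = {"bayesw": __version__, "numpy": np.__version__}
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["manifest_hash"] = hashlib.sha256(blob.encode()).hexdigest()
    path = out / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path
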