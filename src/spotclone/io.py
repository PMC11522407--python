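"""Readers and writers for the plain-text data formats.

Dense matrices travel as TSV with a header row of clone/spot labels and
row labels of mutation identifiers ("chrom:pos:ref>alt", 1-based positions
in the label; internal arrays are 0-indexed). Sparse read-count matrices
may arrive as matrix-market files with label sidecars. Every artifact
directory written by the pipeline includes a JSON manifest recording the
configuration and seed needed to regenerate it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .inference import PosteriorSummary
from .model import CloneSet, SpotDataset
from .simulate import GroundTruth


def write_matrix_tsv(
    path: Path | str,
    mat: np.ndarray,
    row_labels: list[str],
    col_labels: list[str],
) -> None:
    pd.DataFrame(mat, index=row_labels, columns=col_labels).to_csv(path, sep="\t")


def read_matrix_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_matrix_any(path: Path | str) -> pd.DataFrame:
    """Read a labelled matrix from TSV, or MTX with .rows/.cols sidecars."""
    path = Path(path)
    if path.suffix == ".mtx":
        m = mmread(path)
        mat = m.toarray() if hasattr(m, "toarray") else np.asarray(m)
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        return pd.DataFrame(mat, index=rows, columns=cols)
    return read_matrix_tsv(path)


def write_matrix_mtx(
    path: Path | str,
    mat: np.ndarray,
    row_labels: list[str],
    col_labels: list[str],
) -> None:
    mmwrite(str(path), csr_matrix(mat))
    # mmwrite appends .mtx if missing; normalize
    path = Path(path if str(path).endswith(".mtx") else str(path) + ".mtx")
    Path(str(path) + ".rows").write_text("\n".join(row_labels) + "\n")
    Path(str(path) + ".cols").write_text("\n".join(col_labels) + "\n")


def default_mutation_labels(M: int) -> list[str]:
    return [f"chr1:{1000 + 10 * i}:A>T" for i in range(M)]


def default_spot_labels(coords: np.ndarray) -> list[str]:
    return [f"{x}x{y}" for x, y in np.asarray(coords)]


def load_spot_dataset(
    a_path: Path | str,
    d_path: Path | str,
    coords_path: Path | str,
    cells_path: Path | str,
) -> SpotDataset:
    """Load and cross-validate a spot dataset from its four files.

    A and D are reconciled by mutation/spot label, not file position; a
    label mismatch or any A > D entry is a validation error naming the
    offenders.
    """
    A = read_matrix_any(a_path)
    D = read_matrix_any(d_path)
    if set(A.index) != set(D.index) or set(A.columns) != set(D.columns):
        missing = sorted(set(A.index) ^ set(D.index)) + sorted(
            set(A.columns) ^ set(D.columns)
        )
        raise ValueError(f"A/D label mismatch: {missing[:10]}")
    A = A.loc[D.index, D.columns]
    coords_df = pd.read_csv(coords_path, sep="\t", index_col=0)
    cells_df = pd.read_csv(cells_path, sep="\t", index_col=0)
    coords_df = coords_df.loc[list(D.columns)]
    cells_df = cells_df.loc[list(D.columns)]
    return SpotDataset(
        A=A.to_numpy(dtype=np.int64),
        D=D.to_numpy(dtype=np.int64),
        coords=coords_df.to_numpy(dtype=int),
        n_prior=cells_df.to_numpy().ravel().astype(np.int64),
        labels_mutations=list(D.index),
        labels_spots=list(D.columns),
    )


def load_clone_set(
    c_path: Path | str, f_path: Path | str, F0: float = 0.01, l: float = 100.0
) -> CloneSet:
    C = read_matrix_any(c_path)
    F = pd.read_csv(f_path, sep="\t", index_col=0)
    F = F.loc[list(C.columns)]
    return CloneSet(
        C=C.to_numpy(dtype=float),
        F=F.to_numpy().ravel(),
        F0=F0,
        l=l,
        labels_mutations=list(C.index),
        labels_clones=list(C.columns),
    )


def write_dataset(
    outdir: Path | str,
    data: SpotDataset,
    clones: CloneSet,
    truth: GroundTruth | None = None,
    manifest: dict | None = None,
) -> Path:
    """Write a dataset directory (A/D/C/F/coords/cell counts [+ truth])."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mut = data.labels_mutations or default_mutation_labels(data.n_mutations)
    spots = data.labels_spots or default_spot_labels(data.coords)
    k_labels = clones.labels_clones or [
        f"clone{k}" for k in range(clones.n_clones)
    ]
    write_matrix_tsv(outdir / "A.tsv", data.A, mut, spots)
    write_matrix_tsv(outdir / "D.tsv", data.D, mut, spots)
    write_matrix_tsv(outdir / "C.tsv", clones.C, mut, k_labels)
    pd.DataFrame({"F": clones.F}, index=k_labels).to_csv(
        outdir / "F.tsv", sep="\t"
    )
    pd.DataFrame(data.coords, index=spots, columns=["x", "y"]).to_csv(
        outdir / "coords.tsv", sep="\t"
    )
    pd.DataFrame({"n_cells": data.n_prior}, index=spots).to_csv(
        outdir / "n_cells.tsv", sep="\t"
    )
    if truth is not None:
        tdir = outdir / "truth"
        tdir.mkdir(exist_ok=True)
        write_matrix_tsv(tdir / "H_true.tsv", truth.H_true, spots, k_labels)
        write_matrix_tsv(
            tdir / "Z_true.tsv", truth.Z_true.astype(int), spots, k_labels
        )
        pd.DataFrame({"N_true": truth.N_true}, index=spots).to_csv(
            tdir / "N_true.tsv", sep="\t"
        )
    if manifest is not None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def write_posterior(
    outdir: Path | str,
    summary: PosteriorSummary,
    spot_labels: list[str],
    clone_labels: list[str],
    mutation_labels: list[str],
    manifest: dict | None = None,
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(
        outdir / "clone_proportions.tsv", summary.H_mean, spot_labels, clone_labels
    )
    pd.DataFrame({"N_mean": summary.N_mean}, index=spot_labels).to_csv(
        outdir / "cell_counts.tsv", sep="\t"
    )
    write_matrix_tsv(
        outdir / "phi_mean.tsv", summary.Phi_mean, mutation_labels, clone_labels
    )
    report = {
        "acceptance_rates": summary.accept_rates,
        "n_samples": summary.n_samples,
        "proposal_sigmas": summary.sigmas,
    }
    (outdir / "sampler_report.json").write_text(json.dumps(report, indent=2))
    if manifest is not None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
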