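"""Support for a STRUCTURE-based clustering workflow: parse replicate run
logs, compute the Evanno delta-K statistic to choose the number of clusters,
and tabulate mean ancestry per population with label-switching alignment.

The MCMC admixture inference itself is external; this module only writes
parameter files for it (``write_structure_params``), parses its results
format and post-processes replicate runs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StructureRun",
    "DeltaKTable",
    "parse_structure_output",
    "evanno_delta_k",
    "ancestry_by_population",
    "write_structure_params",
]

_LNPROB_RE = re.compile(r"Estimated Ln Prob of Data\s*=\s*(-?\d+(?:\.\d+)?)")


@dataclass
class StructureRun:
    K: int
    replicate: int
    ln_prob: float
    labels: list[str]  # individual labels in file order
    q_matrix: np.ndarray  # individuals x K ancestry proportions
    source: str = ""


@dataclass
class DeltaKTable:
    table: pd.DataFrame  # columns: K, mean_ln_prob, sd_ln_prob, delta_k

    @property
    def best_k(self) -> int:
        interior = self.table.dropna(subset=["delta_k"])
        return int(interior.loc[interior["delta_k"].idxmax(), "K"])


def _parse_one(path) -> tuple[float, list[str], np.ndarray]:
    text = Path(path).read_text()
    m = _LNPROB_RE.search(text)
    if m is None:
        raise ValueError(f"{path}: no 'Estimated Ln Prob of Data' line found")
    ln_prob = float(m.group(1))

    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if "Inferred ancestry of individuals" in line:
            start = i
            break
    if start is None:
        raise ValueError(f"{path}: no 'Inferred ancestry of individuals' block found")
    labels: list[str] = []
    rows: list[list[float]] = []
    for line in lines[start + 1 :]:
        stripped = line.strip()
        if not stripped:
            if rows:
                break
            continue
        if ":" not in stripped:
            if rows:
                break
            continue  # the 'Label (%Miss) Pop' header line
        left, right = stripped.split(":", 1)
        try:
            q = [float(tok) for tok in right.split()]
        except ValueError:
            if not rows:  # the 'Label (%Miss) Pop: Inferred clusters' header
                continue
            raise ValueError(f"{path}: malformed ancestry row {stripped!r}") from None
        left_tokens = left.split()
        label = left_tokens[1] if len(left_tokens) > 1 else left_tokens[0]
        total = sum(q)
        if abs(total - 1.0) > 1e-3:
            raise ValueError(
                f"{path}: ancestry row for {label!r} sums to {total}, beyond tolerance"
            )
        if total > 0:
            q = [v / total for v in q]
        labels.append(label)
        rows.append(q)
    if not rows:
        raise ValueError(f"{path}: empty ancestry block")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ancestry rows have inconsistent cluster counts {widths}")
    return ln_prob, labels, np.array(rows)


def parse_structure_output(paths) -> list[StructureRun]:
    """Parse STRUCTURE results files, one run per file.

    K is inferred from the width of the ancestry block; replicate numbers
    are assigned in path order within each K.
    """
    runs: list[StructureRun] = []
    counter: dict[int, int] = {}
    for path in paths:
        ln_prob, labels, q = _parse_one(path)
        K = q.shape[1]
        rep = counter.get(K, 0)
        counter[K] = rep + 1
        runs.append(
            StructureRun(
                K=K, replicate=rep, ln_prob=ln_prob, labels=labels, q_matrix=q,
                source=str(path),
            )
        )
    return runs


def evanno_delta_k(runs) -> DeltaKTable:
    """Evanno's delta-K over replicate runs.

    delta_K(K) = mean over replicates of |L(K+1) - 2 L(K) + L(K-1)|,
    divided by the (sample) SD of L(K) over replicates.  Defined for
    interior K only; requires a consecutive K range of length >= 3 and
    >= 2 replicates per K, paired by replicate index.
    """
    by_k: dict[int, dict[int, float]] = {}
    for run in runs:
        by_k.setdefault(run.K, {})[run.replicate] = run.ln_prob
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"need a consecutive K range of length >= 3, got {ks}")
    n_rep = {k: len(v) for k, v in by_k.items()}
    if min(n_rep.values()) < 2:
        raise ValueError(f"need >= 2 replicates per K, got {n_rep}")
    rep_ids = set.intersection(*(set(v) for v in by_k.values()))
    if len(rep_ids) < 2:
        raise ValueError("replicate indices do not align across K values")
    rep_ids = sorted(rep_ids)
    L = np.array([[by_k[k][r] for k in ks] for r in rep_ids])  # reps x K

    mean_l = L.mean(axis=0)
    sd_l = L.std(axis=0, ddof=1)
    delta = np.full(len(ks), np.nan)
    for j in range(1, len(ks) - 1):
        second = L[:, j + 1] - 2.0 * L[:, j] + L[:, j - 1]
        if sd_l[j] == 0.0:
            raise ValueError(
                f"sd of ln-prob is 0 at K={ks[j]}; add replicates or jitter — "
                "delta-K would divide by zero"
            )
        delta[j] = np.mean(np.abs(second)) / sd_l[j]
    table = pd.DataFrame(
        {"K": ks, "mean_ln_prob": mean_l, "sd_ln_prob": sd_l, "delta_k": delta}
    )
    return DeltaKTable(table=table)


def _align_columns(reference: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    """Greedy column matching on correlation against a reference run,
    to undo label switching.  Returns the permuted matrix and the minimum
    matched correlation."""
    K = q.shape[1]
    corr = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            a, b = reference[:, i], q[:, j]
            sa, sb = a.std(), b.std()
            corr[i, j] = 1.0 if sa == 0 and sb == 0 else (
                0.0 if sa == 0 or sb == 0 else float(np.corrcoef(a, b)[0, 1])
            )
    perm = [-1] * K
    used_rows, used_cols = set(), set()
    min_corr = 1.0
    flat = sorted(
        ((corr[i, j], i, j) for i in range(K) for j in range(K)), reverse=True
    )
    for c, i, j in flat:
        if i in used_rows or j in used_cols:
            continue
        perm[i] = j
        used_rows.add(i)
        used_cols.add(j)
        min_corr = min(min_corr, c)
        if len(used_rows) == K:
            break
    return q[:, perm], min_corr


def ancestry_by_population(runs, population_of: dict[str, str]) -> pd.DataFrame:
    """Mean ancestry per population over individuals and replicates at one K.

    Cluster labels are aligned across replicates by greedy correlation
    matching to the first run; an alignment correlation below 0.5 triggers
    a warning (possible unresolved label switching).
    """
    runs = list(runs)
    if not runs:
        raise ValueError("no runs given")
    ks = {run.K for run in runs}
    if len(ks) != 1:
        raise ValueError(f"runs mix several K values: {sorted(ks)}")
    ref = runs[0]
    aligned = [ref.q_matrix]
    for run in runs[1:]:
        if run.labels != ref.labels:
            raise ValueError("runs list different individuals or a different order")
        q, min_corr = _align_columns(ref.q_matrix, run.q_matrix)
        if min_corr < 0.5:
            warnings.warn(
                f"label alignment correlation {min_corr:.2f} < 0.5 for run "
                f"{run.source or run.replicate}; label switching may be unresolved",
                stacklevel=2,
            )
        aligned.append(q)
    mean_q = np.mean(aligned, axis=0)  # individuals x K

    unknown = [lab for lab in ref.labels if lab not in population_of]
    if unknown:
        raise ValueError(f"individuals without population assignment: {unknown[:5]}")
    frame = pd.DataFrame(
        mean_q, index=ref.labels, columns=[f"cluster_{k + 1}" for k in range(ref.K)]
    )
    frame["population"] = [population_of[lab] for lab in ref.labels]
    out = frame.groupby("population").mean()
    return out.div(out.sum(axis=1), axis=0)


def write_structure_params(
    outdir,
    n_individuals: int,
    n_loci: int,
    ploidy: int,
    burnin: int = 10_000,
    numreps: int = 100_000,
) -> tuple[Path, Path]:
    """Write mainparams/extraparams for an external STRUCTURE run
    (admixture model, no prior population information)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mainparams = outdir / "mainparams"
    extraparams = outdir / "extraparams"
    mainparams.write_text(
        "\n".join(
            [
                f"#define BURNIN {burnin}",
                f"#define NUMREPS {numreps}",
                f"#define NUMINDS {n_individuals}",
                f"#define NUMLOCI {n_loci}",
                f"#define PLOIDY {ploidy}",
                "#define MISSING -9",
                "#define ONEROWPERIND 0",
                "#define LABEL 1",
                "#define POPDATA 1",
                "#define POPFLAG 0",
                "#define LOCDATA 0",
                "#define PHENOTYPE 0",
                "#define EXTRACOLS 0",
                "#define MARKERNAMES 0",
                "",
            ]
        )
    )
    extraparams.write_text(
        "\n".join(
            [
                "#define NOADMIX 0",  # admixture model
                "#define LINKAGE 0",
                "#define USEPOPINFO 0",
                "#define INFERALPHA 1",
                "",
            ]
        )
    )
    return mainparams, extraparams
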