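"""Reading multilocus datasets and writing MCMC traces and posterior summaries.

Datasets are collections of population-labeled alignments, one per locus,
each tagged with its mutation model (HKY or IS) and a relative mutation
scale u.  Two input dialects are supported:

im-text (native, block-structured)
    line 1: number of loci.  Per locus: a header line
    ``name N1 N2 n model u [ancestral_row]`` followed by N1+N2 lines
    ``label sequence`` (label in {1, 2}; population 1 rows first), and for
    IS loci optionally one trailing line ``anc <sequence>`` giving the
    ancestral allele at every site (used when the ancestral state is not
    one of the sampled rows, as for simulated data).

fasta+popmap
    a directory with one ``<name>.fasta`` per locus and a two-column
    ``popmap.tsv`` (sequence id, TAB, label).  A label of ``anc`` marks a
    row as the ancestral designation and tags the locus IS.

Only A/C/G/T are accepted; ambiguity codes and gaps are rejected because
the likelihoods are defined only over the four-letter alphabet.  Traces and
posterior summaries are written as TSV with full float precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .im_parameters import PARAM_NAMES, IMParameters, PriorSpec

__all__ = [
    "Locus",
    "Dataset",
    "TraceRecord",
    "ParseError",
    "read_dataset",
    "write_dataset",
    "read_trace",
    "write_trace",
    "write_summary",
    "encode_sequence",
    "decode_sequence",
]

_CODE = {c: i for i, c in enumerate("ACGT")}
_CHAR = np.array(list("ACGT"))


class ParseError(ValueError):
    """Malformed dataset file; the message names the offending line."""


def encode_sequence(s: str) -> np.ndarray:
    """String of A/C/G/T to codes 0..3."""
    try:
        return np.array([_CODE[c] for c in s.upper()], dtype=np.uint8)
    except KeyError as e:
        raise ParseError(f"non-ACGT character {e.args[0]!r} in sequence") from None


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(_CHAR[codes])


@dataclass(eq=False)
class Locus:
    """One aligned locus with population labels and a mutation-model tag.

    alignment : (N, n) uint8 codes 0..3, population-1 rows first.
    pop_labels : (N,) int in {1, 2}.
    model : "HKY" or "IS".
    u : relative per-locus mutation scale (dimensionless, default 1).
    ancestral_row : optional row index whose alleles are ancestral (IS).
    ancestral_seq : optional (n,) uint8 explicit ancestral sequence (IS).
    """

    name: str
    alignment: np.ndarray
    pop_labels: np.ndarray
    model: str = "HKY"
    u: float = 1.0
    ancestral_row: int | None = None
    ancestral_seq: np.ndarray | None = None

    def __post_init__(self):
        self.alignment = np.asarray(self.alignment, dtype=np.uint8)
        self.pop_labels = np.asarray(self.pop_labels, dtype=np.int64)
        self.validate()

    @property
    def N(self) -> int:
        return self.alignment.shape[0]

    @property
    def n(self) -> int:
        return self.alignment.shape[1]

    @property
    def N1(self) -> int:
        return int(np.sum(self.pop_labels == 1))

    @property
    def N2(self) -> int:
        return int(np.sum(self.pop_labels == 2))

    @property
    def ancestral(self):
        """Ancestral codes per site, or None."""
        if self.ancestral_seq is not None:
            return self.ancestral_seq
        if self.ancestral_row is not None:
            return self.alignment[self.ancestral_row]
        return None

    def validate(self):
        if self.alignment.ndim != 2 or self.alignment.shape[1] < 1:
            raise ValueError(f"locus {self.name}: alignment must be 2-D with >=1 site")
        if np.any(self.alignment > 3):
            raise ValueError(f"locus {self.name}: alignment codes must be 0..3")
        if self.pop_labels.shape != (self.alignment.shape[0],):
            raise ValueError(f"locus {self.name}: one population label per sequence")
        if not set(np.unique(self.pop_labels)) <= {1, 2}:
            raise ValueError(f"locus {self.name}: population labels must be 1 or 2")
        if self.N1 < 1 or self.N2 < 1:
            raise ValueError(f"locus {self.name}: need >=1 sequence per population")
        if np.any(self.pop_labels[: self.N1] != 1):
            raise ValueError(f"locus {self.name}: population-1 rows must come first")
        if self.model not in ("HKY", "IS"):
            raise ValueError(f"locus {self.name}: unknown model {self.model!r}")
        if self.u <= 0:
            raise ValueError(f"locus {self.name}: mutation scale u must be positive")
        if self.ancestral_row is not None and not (0 <= self.ancestral_row < self.N):
            raise ValueError(f"locus {self.name}: ancestral_row out of range")
        if self.ancestral_seq is not None and self.ancestral_seq.shape != (self.n,):
            raise ValueError(f"locus {self.name}: ancestral sequence length mismatch")


@dataclass(eq=False)
class Dataset:
    """Ordered collection of loci with free-text provenance."""

    loci: list[Locus]
    metadata: str = ""

    def __post_init__(self):
        if not self.loci:
            raise ValueError("dataset must contain at least one locus")
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")


def _equal_locus(a: Locus, b: Locus) -> bool:
    anc_a, anc_b = a.ancestral, b.ancestral
    anc_eq = (anc_a is None and anc_b is None) or (
        anc_a is not None and anc_b is not None and np.array_equal(anc_a, anc_b)
    )
    return (
        a.name == b.name
        and np.array_equal(a.alignment, b.alignment)
        and np.array_equal(a.pop_labels, b.pop_labels)
        and a.model == b.model
        and a.u == b.u
        and anc_eq
    )


def datasets_equal(a: Dataset, b: Dataset) -> bool:
    return len(a.loci) == len(b.loci) and all(
        _equal_locus(x, y) for x, y in zip(a.loci, b.loci)
    )


# ---------------------------------------------------------------------------
# im-text dialect


def _parse_im_text(path: Path) -> Dataset:
    lines = path.read_text().splitlines()
    pos = 0

    def next_line() -> tuple[str, int]:
        nonlocal pos
        while pos < len(lines) and not lines[pos].strip():
            pos += 1
        if pos >= len(lines):
            raise ParseError(f"{path}: unexpected end of file")
        pos += 1
        return lines[pos - 1], pos

    head, ln = next_line()
    try:
        n_loci = int(head.split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}:{ln}: expected locus count") from None
    if n_loci < 1:
        raise ParseError(f"{path}:{ln}: need at least one locus")
    loci = []
    for _ in range(n_loci):
        header, ln = next_line()
        parts = header.split()
        if len(parts) not in (6, 7):
            raise ParseError(
                f"{path}:{ln}: locus header must be 'name N1 N2 n model u [ancestral_row]'"
            )
        name = parts[0]
        try:
            N1, N2, n = int(parts[1]), int(parts[2]), int(parts[3])
            u = float(parts[5])
        except ValueError:
            raise ParseError(f"{path}:{ln}: malformed locus header") from None
        model = parts[4]
        if model not in ("HKY", "IS"):
            raise ParseError(f"{path}:{ln}: unknown model tag {model!r}")
        ancestral_row = None
        if len(parts) == 7:
            try:
                ancestral_row = int(parts[6])
            except ValueError:
                raise ParseError(f"{path}:{ln}: malformed ancestral_row") from None
        rows = []
        labels = []
        for _ in range(N1 + N2):
            line, ln = next_line()
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}:{ln}: expected 'label sequence'")
            if fields[0] not in ("1", "2"):
                raise ParseError(f"{path}:{ln}: population label must be 1 or 2")
            labels.append(int(fields[0]))
            if len(fields[1]) != n:
                raise ParseError(
                    f"{path}:{ln}: sequence length {len(fields[1])} != declared n={n}"
                )
            try:
                rows.append(encode_sequence(fields[1]))
            except ParseError as e:
                raise ParseError(f"{path}:{ln}: {e}") from None
        ancestral_seq = None
        if pos < len(lines):
            peek = lines[pos].split()
            if peek and peek[0] == "anc":
                line, ln = next_line()
                fields = line.split()
                if len(fields) != 2 or len(fields[1]) != n:
                    raise ParseError(f"{path}:{ln}: malformed ancestral line")
                ancestral_seq = encode_sequence(fields[1])
        try:
            loci.append(
                Locus(
                    name,
                    np.vstack(rows),
                    np.array(labels),
                    model,
                    u,
                    ancestral_row,
                    ancestral_seq,
                )
            )
        except ValueError as e:
            raise ParseError(f"{path}: locus {name}: {e}") from None
    return Dataset(loci, metadata=str(path))


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset in the im-text dialect."""
    path = Path(path)
    out = [str(len(dataset.loci))]
    for loc in dataset.loci:
        header = f"{loc.name} {loc.N1} {loc.N2} {loc.n} {loc.model} {loc.u:.17g}"
        if loc.ancestral_row is not None:
            header += f" {loc.ancestral_row}"
        out.append(header)
        for i in range(loc.N):
            out.append(f"{int(loc.pop_labels[i])} {decode_sequence(loc.alignment[i])}")
        if loc.ancestral_seq is not None:
            out.append(f"anc {decode_sequence(loc.ancestral_seq)}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# fasta + popmap dialect


def _parse_fasta(path: Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            if name is None:
                raise ParseError(f"{path}:{ln}: sequence data before first header")
            chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    if not seqs:
        raise ParseError(f"{path}: no sequences found")
    return seqs


def _parse_fasta_popmap(directory: Path) -> Dataset:
    popmap_path = directory / "popmap.tsv"
    if not popmap_path.exists():
        raise ParseError(f"{directory}: missing popmap.tsv")
    labels: dict[str, str] = {}
    for ln, line in enumerate(popmap_path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{popmap_path}:{ln}: expected 'id<TAB>label'")
        if fields[1] not in ("1", "2", "anc"):
            raise ParseError(f"{popmap_path}:{ln}: label must be 1, 2 or anc")
        labels[fields[0]] = fields[1]
    loci = []
    for fasta in sorted(directory.glob("*.fasta")):
        seqs = _parse_fasta(fasta)
        missing = [k for k in seqs if k not in labels]
        if missing:
            raise ParseError(f"{fasta}: sequence {missing[0]!r} missing from popmap")
        anc_ids = [k for k in seqs if labels[k] == "anc"]
        sample_ids = sorted(
            (k for k in seqs if labels[k] != "anc"), key=lambda k: (labels[k], k)
        )
        lens = {len(seqs[k]) for k in seqs}
        if len(lens) != 1:
            raise ParseError(f"{fasta}: ragged alignment")
        rows = np.vstack([encode_sequence(seqs[k]) for k in sample_ids])
        pops = np.array([int(labels[k]) for k in sample_ids])
        ancestral_seq = encode_sequence(seqs[anc_ids[0]]) if anc_ids else None
        model = "IS" if anc_ids else "HKY"
        loci.append(Locus(fasta.stem, rows, pops, model, 1.0, None, ancestral_seq))
    if not loci:
        raise ParseError(f"{directory}: no .fasta files found")
    return Dataset(loci, metadata=str(directory))


def read_dataset(path, format: str = "im-text") -> Dataset:
    """Read a multilocus dataset in the named dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "im-text":
        return _parse_im_text(path)
    if format == "fasta+popmap":
        return _parse_fasta_popmap(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# traces and summaries


@dataclass
class TraceRecord:
    """One sampled state of the cold chain."""

    generation: int
    params: IMParameters
    loglik_per_locus: list[float]
    loglik_total: float
    logprior: float
    chain_id: int = 0
    beta: float = 1.0
    accept_counts: dict[str, tuple[int, int]] = field(default_factory=dict)


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def write_trace(records: list[TraceRecord], path) -> None:
    """Tab-separated trace, one row per record, full float precision."""
    if not records:
        raise ValueError("cannot write an empty trace")
    n_loci = len(records[0].loglik_per_locus)
    for r in records:
        if len(r.loglik_per_locus) != n_loci:
            raise ValueError("records have inhomogeneous per-locus columns")
    cols = (
        ["generation"]
        + list(PARAM_NAMES)
        + [f"loglik_{i}" for i in range(n_loci)]
        + ["loglik_total", "logprior", "chain_id", "beta", "accepts"]
    )
    rows = []
    for r in records:
        acc = ";".join(f"{k}:{a}/{p}" for k, (a, p) in sorted(r.accept_counts.items()))
        rows.append(
            [str(r.generation)]
            + [_fmt(getattr(r.params, k)) for k in PARAM_NAMES]
            + [_fmt(v) for v in r.loglik_per_locus]
            + [_fmt(r.loglik_total), _fmt(r.logprior), str(r.chain_id), _fmt(r.beta), acc]
        )
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_trace(path) -> list[TraceRecord]:
    """Read back a trace written by :func:`write_trace`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    lcols = [c for c in df.columns if c.startswith("loglik_") and c != "loglik_total"]
    records = []
    for _, row in df.iterrows():
        acc = {}
        if isinstance(row.get("accepts"), str) and row["accepts"]:
            for item in row["accepts"].split(";"):
                k, v = item.split(":")
                a, p = v.split("/")
                acc[k] = (int(a), int(p))
        records.append(
            TraceRecord(
                generation=int(row["generation"]),
                params=IMParameters(*(float(row[k]) for k in PARAM_NAMES)),
                loglik_per_locus=[float(row[c]) for c in lcols],
                loglik_total=float(row["loglik_total"]),
                logprior=float(row["logprior"]),
                chain_id=int(row["chain_id"]),
                beta=float(row["beta"]),
                accept_counts=acc,
            )
        )
    return records


def write_summary(
    records: list[TraceRecord], priors: PriorSpec, bins: int, path
) -> pd.DataFrame:
    """Posterior mean, histogram mode and central 90% interval per parameter.

    The mode is the midpoint of the highest-count bin of an equal-width
    histogram over [0, prior bound].  Returns the summary table after
    writing it as TSV.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if not records:
        raise ValueError("cannot summarize an empty trace")
    rows = []
    for name in PARAM_NAMES:
        x = np.array([getattr(r.params, name) for r in records])
        bound = priors.bound(name)
        hist, edges = np.histogram(x, bins=bins, range=(0.0, bound))
        k = int(np.argmax(hist))
        mode = 0.5 * (edges[k] + edges[k + 1])
        lo, hi = np.quantile(x, [0.05, 0.95])
        rows.append(
            {
                "parameter": name,
                "mean": float(x.mean()),
                "mode": float(mode),
                "q05": float(lo),
                "q95": float(hi),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return df
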