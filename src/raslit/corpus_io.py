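"""Reading, validating and persisting corpora, gene dictionaries and matrices.

Containers for the pipeline's inputs — a document corpus, a gene synonym
dictionary with known pathway memberships, and the pathway→branch registry —
plus lossless MatrixMarket persistence for the gene × document feature matrix.

All ordering is canonical (lexicographic by doc_id / gene_id) so that every
matrix built from the same files is reproducible entry-for-entry.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

#: Pathway → disease-branch grouping for the ten renin-angiotensin-system
#: pathways: the RAS cascade itself, renin secretion, aldosterone synthesis/
#: secretion, aldosterone-regulated sodium reabsorption, estrogen signalling
#: and vasopressin-regulated water reabsorption are hypertension-related;
#: diabetic cardiomyopathy and AGE-RAGE signalling are diabetes-related;
#: hypertrophic and dilated cardiomyopathy are cardiac-disease-related.
DEFAULT_BRANCH_MAP: dict[str, str] = {
    "RAS": "hypertension",
    "RS": "hypertension",
    "AS": "hypertension",
    "ARSR": "hypertension",
    "ESP": "hypertension",
    "VRWR": "hypertension",
    "DiCM": "diabetes",
    "AGE-RAGE": "diabetes",
    "HCM": "cardiac",
    "DCM": "cardiac",
}

BRANCH_IDS = ("hypertension", "cardiac", "diabetes")


class CorpusError(ValueError):
    """Raised when a corpus, dictionary or matrix fails validation."""


@dataclass
class Document:
    """One full-text document identified by an opaque id (e.g. a PMID)."""

    doc_id: str
    text: str
    tokens: list[str] | None = None


@dataclass
class Corpus:
    """An ordered, doc_id-sorted collection of documents (the D of IDF)."""

    documents: list[Document]

    def __post_init__(self) -> None:
        self.documents = sorted(self.documents, key=lambda d: d.doc_id)
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise CorpusError(f"duplicate doc_id: {doc.doc_id!r}")
            seen.add(doc.doc_id)

    @property
    def N(self) -> int:
        return len(self.documents)

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]

    def __iter__(self):
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)


@dataclass
class GeneDictionary:
    """gene_id → synonym phrases + known pathway memberships.

    Rows of the feature matrix and the source of the ground-truth labels.
    Entries are kept sorted by gene_id.
    """

    entries: list[tuple[str, list[str], set[str]]]
    registry: "PathwayRegistry"

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e[0])
        seen: set[str] = set()
        known = set(self.registry.pathway_ids)
        for gene_id, synonyms, pathways in self.entries:
            if gene_id in seen:
                raise CorpusError(f"duplicate gene_id: {gene_id!r}")
            seen.add(gene_id)
            if not synonyms or all(not s.strip() for s in synonyms):
                raise CorpusError(f"gene {gene_id!r} has no synonyms")
            unknown = set(pathways) - known
            if unknown:
                raise CorpusError(
                    f"gene {gene_id!r} references unregistered pathway(s): "
                    f"{sorted(unknown)}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def label_matrix(self) -> "LabelMatrix":
        """Binary gene × pathway membership matrix from the known annotations."""
        from .models import LabelMatrix  # local import to avoid a cycle

        pathways = self.registry.pathway_ids
        col = {p: j for j, p in enumerate(pathways)}
        values = np.zeros((len(self.entries), len(pathways)), dtype=np.int8)
        for i, (_, _, pws) in enumerate(self.entries):
            for p in pws:
                values[i, col[p]] = 1
        return LabelMatrix(values=values, gene_ids=self.gene_ids,
                           pathway_ids=list(pathways))


@dataclass
class PathwayRegistry:
    """Ordered pathway ids plus the pathway → disease-branch grouping."""

    pathway_ids: list[str]
    branch_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.pathway_ids)) != len(self.pathway_ids):
            raise CorpusError("duplicate pathway ids in registry")
        missing = [p for p in self.pathway_ids if p not in self.branch_map]
        if self.branch_map and missing:
            raise CorpusError(f"pathways missing from branch_map: {missing}")

    @property
    def branch_ids(self) -> list[str]:
        # Stable branch order: canonical triple first, then anything extra.
        seen = list(dict.fromkeys(self.branch_map[p] for p in self.pathway_ids))
        ordered = [b for b in BRANCH_IDS if b in seen]
        return ordered + [b for b in seen if b not in ordered]

    @classmethod
    def default(cls) -> "PathwayRegistry":
        return cls(pathway_ids=list(DEFAULT_BRANCH_MAP),
                   branch_map=dict(DEFAULT_BRANCH_MAP))


@dataclass
class FeatureMatrix:
    """Sparse non-negative gene × document TF-IDF matrix with its indices."""

    values: sp.csr_matrix
    gene_ids: list[str]
    doc_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.doc_ids)):
            raise CorpusError(
                f"matrix shape {self.values.shape} does not match index "
                f"lengths ({len(self.gene_ids)}, {len(self.doc_ids)})"
            )
        data = self.values.data
        if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
            raise CorpusError("feature matrix must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def toarray(self) -> np.ndarray:
        return self.values.toarray()


# ---------------------------------------------------------------------------
# Corpus loading


def load_corpus(path: str | Path, format: str = "auto") -> Corpus:
    """Load a corpus from a directory of .txt files or a JSONL file.

    txt-dir: one UTF-8 ``<doc_id>.txt`` file per document. jsonl: one JSON
    object per line with ``doc_id`` and ``text`` keys. Documents whose text is
    empty after stripping are dropped with a logged count; duplicate doc_ids
    and an empty result are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "txt-dir" if path.is_dir() else "jsonl"

    records: list[tuple[str, str]] = []
    if format == "txt-dir":
        for f in sorted(path.glob("*.txt")):
            records.append((f.stem, f.read_text(encoding="utf-8")))
    elif format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                records.append((str(obj["doc_id"]), str(obj["text"])))
    else:
        raise ValueError(f"unknown corpus format: {format!r}")

    seen: set[str] = set()
    for doc_id, _ in records:
        if doc_id in seen:
            raise CorpusError(f"duplicate doc_id: {doc_id!r}")
        seen.add(doc_id)

    kept = [Document(doc_id, text) for doc_id, text in records if text.strip()]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.warning("dropped %d empty document(s)", n_dropped)
    if not kept:
        raise CorpusError(f"no readable non-empty documents under {path}")
    return Corpus(documents=kept)


def save_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(json.dumps({"doc_id": doc.doc_id, "text": doc.text}) + "\n")


# ---------------------------------------------------------------------------
# Gene dictionary and registry I/O


def load_pathway_registry(path: str | Path | None = None) -> PathwayRegistry:
    """Load a pathway_id / branch_id TSV, or the packaged default registry."""
    if path is None:
        return PathwayRegistry.default()
    pathway_ids: list[str] = []
    branch_map: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["pathway_id", "branch_id"]:
            raise CorpusError("registry TSV must have columns pathway_id, branch_id")
        for line in fh:
            if not line.strip():
                continue
            pid, bid = line.rstrip("\n").split("\t")[:2]
            pathway_ids.append(pid)
            branch_map[pid] = bid
    return PathwayRegistry(pathway_ids=pathway_ids, branch_map=branch_map)


def load_gene_dictionary(path: str | Path,
                         registry: PathwayRegistry | None = None) -> GeneDictionary:
    """Load a gene dictionary TSV: gene_id, synonyms (|-separated), pathways
    (comma-separated). Validation errors (unknown pathway, empty synonym list,
    duplicate gene) are hard errors naming the offender."""
    registry = registry or PathwayRegistry.default()
    entries: list[tuple[str, list[str], set[str]]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene_id", "synonyms", "pathways"]:
            raise CorpusError(
                "dictionary TSV must have columns gene_id, synonyms, pathways")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise CorpusError(f"malformed dictionary row: {line!r}")
            gene_id, syn_field, pw_field = parts[0], parts[1], parts[2]
            synonyms = [s.strip() for s in syn_field.split("|") if s.strip()]
            pathways = {p.strip() for p in pw_field.split(",") if p.strip()}
            entries.append((gene_id, synonyms, pathways))
    return GeneDictionary(entries=entries, registry=registry)


def save_gene_dictionary(dictionary: GeneDictionary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tsynonyms\tpathways\n")
        for gene_id, synonyms, pathways in dictionary:
            fh.write(f"{gene_id}\t{'|'.join(synonyms)}\t{','.join(sorted(pathways))}\n")


# ---------------------------------------------------------------------------
# Feature-matrix persistence (MatrixMarket + row/column sidecars)


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Persist as ``<path>`` MatrixMarket plus ``.rows.txt``/``.cols.txt``
    sidecars carrying the gene and document indices."""
    path = Path(path)
    mmwrite(str(path), sp.coo_matrix(matrix.values))
    base = path.with_suffix("") if path.suffix == ".mtx" else path
    Path(str(base) + ".rows.txt").write_text(
        "\n".join(matrix.gene_ids) + "\n", encoding="utf-8")
    Path(str(base) + ".cols.txt").write_text(
        "\n".join(matrix.doc_ids) + "\n", encoding="utf-8")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    if not path.exists() and path.with_suffix(".mtx").exists():
        path = path.with_suffix(".mtx")
    values = sp.csr_matrix(mmread(str(path)))
    base = path.with_suffix("") if path.suffix == ".mtx" else path
    gene_ids = Path(str(base) + ".rows.txt").read_text(encoding="utf-8").splitlines()
    doc_ids = Path(str(base) + ".cols.txt").read_text(encoding="utf-8").splitlines()
    if values.shape != (len(gene_ids), len(doc_ids)):
        raise CorpusError(
            f"sidecar index lengths ({len(gene_ids)}, {len(doc_ids)}) do not "
            f"match matrix shape {values.shape}")
    return FeatureMatrix(values=values, gene_ids=gene_ids, doc_ids=doc_ids)


def write_label_matrix(labels, path: str | Path) -> None:
    """Persist a binary gene × pathway matrix as a TSV with header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(labels.pathway_ids) + "\n")
        for i, g in enumerate(labels.gene_ids):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in labels.values[i]) + "\n")


def read_label_matrix(path: str | Path):
    from .models import LabelMatrix

    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        pathway_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[int]] = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            gene_ids.append(parts[0])
            rows.append([int(v) for v in parts[1:]])
    return LabelMatrix(values=np.array(rows, dtype=np.int8),
                       gene_ids=gene_ids, pathway_ids=pathway_ids)
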