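"""External representations: FASTA alignments, VCF genotypes, Beagle
genotype likelihoods, metadata tables, newick trees and model JSON.

Conventions used throughout the package:

* VCF positions stay 1-based in user-facing site ids ("<chrom>:<pos>");
  internal arrays are 0-indexed.
* Diploid genotypes are alternate-allele dosages in {0, 1, 2}; missing
  genotypes are ``nan`` in a float matrix, never a -1 sentinel.  A depth
  of zero forces the genotype missing.
* Genotype-likelihood triples are indexed by dosage (index k = likelihood
  that the individual carries k alternate alleles) and renormalized to
  sum to one on read.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import skbio

logger = logging.getLogger("dorsatrace")

#: Controlled vocabulary of sampling regions for COI reference barcodes.
REGIONS = (
    "Africa",
    "East Asia",
    "South Asia",
    "Southeast Asia",
    "Mascarenes",
    "Pacific",
    "Unknown",
)

#: Continental origins a specimen can be assigned to.
ORIGINS = ("Africa", "Asia", "Pacific")

#: Default region → origin mapping.  The Mascarene islands carry an
#: Asian-like genetic signature despite their proximity to Africa, so
#: they count toward Asia.
DEFAULT_ORIGIN_MAP = {
    "Africa": "Africa",
    "East Asia": "Asia",
    "South Asia": "Asia",
    "Southeast Asia": "Asia",
    "Mascarenes": "Asia",
    "Pacific": "Pacific",
}

MODEL_FORMAT_VERSION = "dorsatrace-model-1"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class BarcodeAlignment:
    """An aligned set of haploid mtDNA barcode sequences with region labels.

    Attributes
    ----------
    ids : list of str
        Unique specimen identifiers.
    seqs : list of str
        Upper-case aligned sequences of equal length over IUPAC codes,
        ``-`` (gap) and ``N``.
    region : list of str
        Per-specimen sampling region from :data:`REGIONS`.
    """

    ids: list[str]
    seqs: list[str]
    region: list[str]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sequence id(s): {dupes}")
        if self.seqs:
            width = len(self.seqs[0])
            for idx, s in enumerate(self.seqs):
                if len(s) != width:
                    raise ValueError(
                        f"ragged alignment: record {idx + 1} ({self.ids[idx]!r}) "
                        f"has length {len(s)}, expected {width}"
                    )
        for r in self.region:
            if r not in REGIONS:
                raise ValueError(f"unknown region label {r!r}; expected one of {REGIONS}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def columns(self) -> int:
        """Alignment width (columns are 1-based in user-facing reports)."""
        return len(self.seqs[0]) if self.seqs else 0

    def subset(self, keep: list[int]) -> "BarcodeAlignment":
        return BarcodeAlignment(
            ids=[self.ids[i] for i in keep],
            seqs=[self.seqs[i] for i in keep],
            region=[self.region[i] for i in keep],
        )


@dataclass
class GenotypeTable:
    """Diploid dosage matrix with per-genotype read depth.

    ``geno`` holds alternate-allele dosages 0/1/2 as floats with ``nan``
    for missing; ``depth`` holds non-negative integer read depths of the
    same shape.  Site ids follow the VCF convention ``<chrom>:<pos>``
    with 1-based positions.
    """

    individuals: list[str]
    sites: list[str]
    geno: np.ndarray
    depth: np.ndarray
    class_label: list[str] | None = None
    ref: list[str] | None = None
    alt: list[str] | None = None

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=float)
        self.depth = np.asarray(self.depth, dtype=int)
        if self.geno.shape != self.depth.shape:
            raise ValueError("geno and depth must share shape")
        if self.geno.shape != (len(self.individuals), len(self.sites)):
            raise ValueError("geno shape does not match individuals × sites")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("site ids must be unique")
        if np.any(self.depth < 0):
            raise ValueError("depths must be non-negative")
        # depth 0 forces missing: never let an uncovered genotype into sums
        self.geno = np.where(self.depth == 0, np.nan, self.geno)
        obs = self.geno[~np.isnan(self.geno)]
        if obs.size and not np.isin(obs, [0.0, 1.0, 2.0]).all():
            raise ValueError("genotype dosages must be 0, 1, 2 or missing")

    @property
    def n_ind(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self, site: str) -> int:
        return self.sites.index(site)

    def subset_sites(self, keep: list[int]) -> "GenotypeTable":
        return GenotypeTable(
            individuals=list(self.individuals),
            sites=[self.sites[j] for j in keep],
            geno=self.geno[:, keep].copy(),
            depth=self.depth[:, keep].copy(),
            class_label=list(self.class_label) if self.class_label else None,
            ref=[self.ref[j] for j in keep] if self.ref else None,
            alt=[self.alt[j] for j in keep] if self.alt else None,
        )


@dataclass
class GenotypeLikelihoods:
    """Per-individual, per-site genotype likelihood triples.

    ``gl[i, j, k]`` is the likelihood that individual ``i`` carries
    dosage ``k`` (k alternate alleles) at site ``j``.  Triples are
    normalized to sum to one.
    """

    individuals: list[str]
    sites: list[str]
    gl: np.ndarray

    def __post_init__(self) -> None:
        self.gl = np.asarray(self.gl, dtype=float)
        if self.gl.shape != (len(self.individuals), len(self.sites), 3):
            raise ValueError("gl must have shape (n_ind, n_sites, 3)")
        if np.any(self.gl < 0):
            raise ValueError("genotype likelihoods must be non-negative")
        sums = self.gl.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("genotype likelihood triples must sum to 1")

    @property
    def n_ind(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class OriginCall:
    """A single origin assignment for one specimen by one evidence stream.

    ``origin`` is one of Africa/Asia/Pacific, ``NA`` (uncallable), or an
    ambiguous call carrying ≥2 candidate origins.  ``posterior`` is set
    only for probabilistic methods (COI-DAPC, SNP decision tree).
    """

    specimen: str
    method: str  # "PCA/NJT", "SNPs" or "COI-DAPC"
    origin: str
    posterior: float | None = None
    cluster: int | None = None
    candidates: list[str] = field(default_factory=list)
    reason: str | None = None

    @property
    def is_na(self) -> bool:
        return self.origin == "NA"

    @property
    def is_ambiguous(self) -> bool:
        return self.origin.startswith("ambiguous")


# ---------------------------------------------------------------------------
# FASTA alignment + metadata
# ---------------------------------------------------------------------------

def read_fasta_alignment(path, metadata=None) -> BarcodeAlignment:
    """Read an aligned FASTA file, optionally joining a region metadata TSV.

    The metadata table must carry ``id`` and ``region`` columns; ids not
    present in the table get region ``Unknown``.  Ragged alignments and
    duplicate ids are hard errors.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise ValueError(f"no FASTA records in {path}")

    region_of: dict[str, str] = {}
    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t", dtype=str)
        if "id" not in meta.columns or "region" not in meta.columns:
            raise ValueError("metadata table must have 'id' and 'region' columns")
        region_of = dict(zip(meta["id"], meta["region"].fillna("Unknown")))

    region = [region_of.get(i, "Unknown") for i in ids]
    return BarcodeAlignment(ids=ids, seqs=seqs, region=region)


def write_fasta_alignment(aln: BarcodeAlignment, path, metadata_path=None) -> None:
    """Write an alignment to FASTA, and optionally its region table to TSV."""
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")
    if metadata_path is not None:
        pd.DataFrame({"id": aln.ids, "region": aln.region}).to_csv(
            metadata_path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def read_vcf_genotypes(path) -> GenotypeTable:
    """Read biallelic GT records from a VCF into a :class:`GenotypeTable`.

    Dosage coding is phase- and strand-agnostic (``0|1`` and ``1|0`` both
    map to 1).  Depth comes from per-sample DP, falling back to the sum
    of AD when DP is absent; records with more than one ALT allele are
    dropped with a logged count.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # unreadable file
        raise ValueError(f"cannot read VCF {path}: {exc}") from exc

    individuals = list(vcf.samples)
    sites: list[str] = []
    refs: list[str] = []
    alts: list[str] = []
    geno_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    n_multi = 0

    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gts = v.genotypes  # [[a1, a2, phased], ...]
        if gts is None:
            raise ValueError(f"record {v.CHROM}:{v.POS} has no GT field")
        g = np.full(len(individuals), np.nan)
        for i, alleles in enumerate(gts):
            a = [x for x in alleles[:-1] if x >= 0]
            if len(a) == 2:
                g[i] = float(sum(a))
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            d = dp.reshape(-1).astype(float)
            d[d < 0] = 0  # cyvcf2 encodes missing DP as negative
        else:
            try:
                ad = v.format("AD")
            except KeyError:
                ad = None
            if ad is None:
                d = np.where(np.isnan(g), 0.0, 1.0)  # covered iff called
                logger.debug("no DP/AD at %s:%d; depth set from call status", v.CHROM, v.POS)
            else:
                a = ad.astype(float)
                a[a < 0] = 0
                d = a.sum(axis=1)
                logger.debug("DP absent at %s:%d; using AD sum", v.CHROM, v.POS)
        sites.append(f"{v.CHROM}:{v.POS}")
        refs.append(v.REF)
        alts.append(v.ALT[0])
        geno_cols.append(g)
        depth_cols.append(d.astype(int))

    if n_multi:
        logger.info("dropped %d multiallelic record(s)", n_multi)
    if not sites:
        raise ValueError(f"no biallelic records found in {path}")

    return GenotypeTable(
        individuals=individuals,
        sites=sites,
        geno=np.column_stack(geno_cols),
        depth=np.column_stack(depth_cols),
        ref=refs,
        alt=alts,
    )


# ---------------------------------------------------------------------------
# Beagle genotype likelihoods
# ---------------------------------------------------------------------------

def read_beagle_gl(path) -> GenotypeLikelihoods:
    """Read a Beagle-format GL text file (3 columns per individual).

    The first three columns are marker name and the two alleles; each
    following group of three columns carries one individual's likelihood
    triple, renormalized to sum to one on read.
    """
    df = pd.read_csv(path, sep=r"\s+", header=0)
    n_gl_cols = df.shape[1] - 3
    if n_gl_cols <= 0 or n_gl_cols % 3 != 0:
        raise ValueError(
            f"Beagle file must have 3 GL columns per individual after the "
            f"marker/allele columns; got {df.shape[1]} columns"
        )
    n_ind = n_gl_cols // 3
    # header style "Ind0 Ind0 Ind0"; fall back to positional names
    raw_names = [str(c).split(".")[0] for c in df.columns[3::3]]
    individuals = raw_names if len(set(raw_names)) == n_ind else [f"Ind{i}" for i in range(n_ind)]
    sites = df.iloc[:, 0].astype(str).tolist()
    vals = df.iloc[:, 3:].to_numpy(dtype=float)
    gl = vals.reshape(len(sites), n_ind, 3).transpose(1, 0, 2)
    sums = gl.sum(axis=2, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("encountered an all-zero genotype likelihood triple")
    return GenotypeLikelihoods(individuals=individuals, sites=sites, gl=gl / sums)


def write_beagle_gl(gls: GenotypeLikelihoods, path) -> None:
    """Write genotype likelihoods in Beagle text format."""
    header = ["marker", "allele1", "allele2"]
    for name in gls.individuals:
        header += [name] * 3
    flat = gls.gl.transpose(1, 0, 2).reshape(gls.n_sites, -1)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for j, site in enumerate(gls.sites):
            row = [site, "0", "1"] + [f"{x:.9g}" for x in flat[j]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def write_newick(tree: skbio.TreeNode) -> str:
    """Serialize a tree to a newick string.

    The tree must be connected and acyclic (guaranteed by the TreeNode
    structure) with unique leaf names; re-parsing reproduces topology
    and branch lengths within 1e-9.
    """
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise ValueError("duplicate leaf names in tree")
    if any(n is None for n in names):
        raise ValueError("all leaves must be named")
    import io

    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> skbio.TreeNode:
    """Parse a newick string into a tree."""
    import io

    return skbio.TreeNode.read(io.StringIO(text), format="newick")


# ---------------------------------------------------------------------------
# Model JSON
# ---------------------------------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def save_model_json(payload: dict, path) -> None:
    """Write a model dictionary to JSON with an explicit format-version tag."""
    doc = {"format_version": MODEL_FORMAT_VERSION}
    doc.update(_jsonify(payload))
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model_json(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {doc.get('format_version')!r}"
        )
    return doc
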