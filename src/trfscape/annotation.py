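"""tRF candidate reference construction from a tRNA gene set.

Builds the fragment reference used throughout the pipeline: for every
tRNA gene the mature form (introns spliced out, 3' CCA appended) and the
pre-tRNA 3' trailer are derived, and candidate fragments of three classes
are enumerated over a length range (default 15-30 nt):

* ``five_prime``   - prefixes of the mature sequence (5'-tRFs),
* ``three_prime``  - suffixes of the mature sequence, ending in CCA (3'-tRFs),
* ``three_prime_U`` - leading stretches of the pre-tRNA 3' trailer that end
  in the RNA-polymerase-III poly-U terminator tract (3'U-tRFs).

Candidates with the same class and sequence (multi-copy gene families) are
merged at build time so that read counting downstream is unambiguous.
Internal fragments (i-tRFs) and tRNA halves (>30 nt) are excluded by
construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import io as tio

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
THREE_PRIME_U = "three_prime_U"
TRF_CLASSES = (FIVE_PRIME, THREE_PRIME, THREE_PRIME_U)

CLASS_PREFIX = {FIVE_PRIME: "5'", THREE_PRIME: "3'", THREE_PRIME_U: "3'U"}

_VALID_NT = set("ACGTN")
_ANTICODON_RE = re.compile(r"^[A-Z][a-z]{2}([ACGT]{3})-\d+-\d+$")

# mature tRNAs (with CCA) fall in this length band; anything outside is a
# malformed record, not a tRNA
MATURE_LENGTH_RANGE = (60, 100)


class AnnotationError(ValueError):
    """Malformed tRNA gene record or invalid enumeration parameters."""


@dataclass(frozen=True)
class TrnaGene:
    """One tRNA gene with genomic, mature and trailer sequence forms.

    ``mature_sequence`` is the spliced gene sequence with the
    post-transcriptional 3' CCA; ``trailer_sequence`` is the genomic 3'
    trailer of the pre-tRNA (empty when no trailer annotation was given).
    """

    family_name: str
    isotype: str
    anticodon: str
    is_mitochondrial: bool
    gene_sequence: str
    mature_sequence: str
    trailer_sequence: str


@dataclass
class TrfCandidate:
    """A candidate tRF: named fragment with its generating gene families."""

    name: str
    trf_class: str
    length: int
    sequence: str
    parent_families: frozenset[str]

    @property
    def naming_family(self) -> str:
        return min(self.parent_families)


def _splice(sequence: str, introns) -> str:
    """Remove intron intervals (0-based half-open, on the gene sequence)."""
    if not introns:
        return sequence
    ivs = sorted(introns)
    prev_end = 0
    parts = []
    for start, end in ivs:
        if not (0 <= start < end <= len(sequence)):
            raise AnnotationError(
                f"intron interval ({start}, {end}) outside gene of length {len(sequence)}"
            )
        if start < prev_end:
            raise AnnotationError("overlapping intron intervals")
        parts.append(sequence[prev_end:start])
        prev_end = end
    parts.append(sequence[prev_end:])
    return "".join(parts)


def _parse_header(header: str):
    """Parse a GtRNAdb-style header line (without the '>').

    Layout: ``family [isotype anticodon] [MT] [key=value ...]``. The isotype
    and anticodon may be omitted when the family name encodes them (e.g.
    ``IleAAT-8-1``). Recognised keys: ``trailer=SEQ``, ``cca=genomic``,
    ``introns=start-end[,start-end]`` (1-based inclusive on the gene).
    """
    tokens = header.split()
    if not tokens:
        raise AnnotationError("empty FASTA header")
    family = tokens[0]
    isotype = anticodon = None
    mito = False
    keyvals: dict[str, str] = {}
    positional = []
    for tok in tokens[1:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            keyvals[k.lower()] = v
        elif tok.upper() == "MT":
            mito = True
        else:
            positional.append(tok)
    if len(positional) >= 1:
        isotype = positional[0]
    if len(positional) >= 2:
        anticodon = positional[1].upper()
    m = _ANTICODON_RE.match(family)
    if m:
        encoded = m.group(1)
        if anticodon is not None and anticodon != encoded:
            raise AnnotationError(
                f"record {family!r}: anticodon {anticodon} contradicts family name"
            )
        anticodon = encoded
        if isotype is None:
            isotype = family[:3]
    if isotype is None or anticodon is None:
        raise AnnotationError(
            f"record {family!r}: isotype/anticodon neither in header nor family name"
        )
    if not re.fullmatch(r"[ACGT]{3}", anticodon):
        raise AnnotationError(f"record {family!r}: invalid anticodon {anticodon!r}")
    introns = []
    if "introns" in keyvals:
        for chunk in keyvals["introns"].split(","):
            try:
                a, b = chunk.split("-")
                start, end = int(a) - 1, int(b)  # 1-based inclusive -> half-open
            except ValueError:
                raise AnnotationError(
                    f"record {family!r}: malformed introns field {keyvals['introns']!r}"
                ) from None
            introns.append((start, end))
    return family, isotype, anticodon, mito, keyvals, introns


def load_trna_fasta(
    path,
    trailer_window: int = 50,
    introns_bed=None,
    trailer_fasta=None,
) -> list[TrnaGene]:
    """Load tRNA genes from FASTA and derive mature + trailer forms.

    Parameters
    ----------
    path : str
        tRNA gene FASTA with GtRNAdb-style headers (see ``_parse_header``).
    trailer_window : int
        Number of genomic nucleotides downstream of the gene 3' end carried
        as the pre-tRNA trailer (trailers longer than the window are
        truncated to it).
    introns_bed : str, optional
        BED file (0-based half-open; name column = family) with intron
        intervals on the gene sequence. Header ``introns=`` fields are
        honoured as well.
    trailer_fasta : str, optional
        Companion FASTA of genomic 3' trailers keyed by family name;
        overrides any ``trailer=`` header field.
    """
    bed_introns: dict[str, list[tuple[int, int]]] = {}
    if introns_bed is not None:
        with tio.open_text(introns_bed) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise AnnotationError(f"{introns_bed}: BED line needs 4 columns")
                _chrom, start, end, name = fields[:4]
                bed_introns.setdefault(name, []).append((int(start), int(end)))
    trailers: dict[str, str] = {}
    if trailer_fasta is not None:
        for rid, _desc, seq in tio.read_fasta(trailer_fasta):
            trailers[rid] = seq

    genes: list[TrnaGene] = []
    seen: set[str] = set()
    for rid, desc, seq in tio.read_fasta(path):
        family, isotype, anticodon, mito, keyvals, hdr_introns = _parse_header(desc)
        if family in seen:
            raise AnnotationError(f"duplicate family name {family!r}")
        seen.add(family)
        bad = set(seq) - _VALID_NT
        if bad:
            raise AnnotationError(
                f"record {family!r}: non-ACGTN characters {sorted(bad)}"
            )
        spliced = _splice(seq, bed_introns.get(family, hdr_introns))
        # CCA is appended post-transcriptionally unless the annotation flags
        # a genomically encoded CCA already present at the 3' end
        if keyvals.get("cca") == "genomic" and spliced.endswith("CCA"):
            mature = spliced
        else:
            mature = spliced + "CCA"
        lo, hi = MATURE_LENGTH_RANGE
        if not lo <= len(mature) <= hi:
            raise AnnotationError(
                f"record {family!r}: mature length {len(mature)} outside [{lo}, {hi}]"
            )
        trailer = trailers.get(family, keyvals.get("trailer", ""))
        trailer = trailer.upper()[:trailer_window]
        genes.append(
            TrnaGene(
                family_name=family,
                isotype=isotype,
                anticodon=anticodon,
                is_mitochondrial=mito,
                gene_sequence=seq,
                mature_sequence=mature,
                trailer_sequence=trailer,
            )
        )
    return genes


def name_trf(
    trf_class: str,
    families,
    length: int,
    is_mitochondrial: bool = False,
) -> str:
    """Name a fragment: ``<5'|3'|3'U>-[M-]<family>-L<length>``.

    When several gene families generate the same sequence, the
    lexicographically smallest family names the fragment (the full parent
    set lives on the candidate).
    """
    families = set(families)
    if not families:
        raise AnnotationError("name_trf requires a non-empty family set")
    prefix = CLASS_PREFIX[trf_class]
    mito = "M-" if is_mitochondrial else ""
    return f"{prefix}-{mito}{min(families)}-L{length}"


def enumerate_trf_candidates(
    genes,
    length_range: tuple[int, int] = (15, 30),
    trailer_terminator: str = "TT",
) -> list[TrfCandidate]:
    """Enumerate 5'-, 3'- and 3'U-tRF candidates over a length range.

    For each gene and length L: the mature prefix (5'-tRF), the mature
    suffix (3'-tRF, ends in CCA) and the first L trailer nucleotides
    (3'U-tRF, retained only when terminating in >=2 consecutive T).
    Candidates sharing (class, sequence) are merged; parent families are
    unioned. Output order is deterministic and independent of gene order.
    """
    genes = list(genes)
    if not genes:
        raise AnnotationError("empty gene set")
    lo, hi = length_range
    if not (10 <= lo <= hi <= 35):
        raise AnnotationError(f"length_range {length_range} outside [10, 35]")

    mito_of = {g.family_name: g.is_mitochondrial for g in genes}
    merged: dict[tuple[str, str], set[str]] = {}
    for gene in sorted(genes, key=lambda g: g.family_name):
        mature, trailer = gene.mature_sequence, gene.trailer_sequence
        for L in range(lo, hi + 1):
            if L <= len(mature):
                merged.setdefault((FIVE_PRIME, mature[:L]), set()).add(gene.family_name)
                merged.setdefault((THREE_PRIME, mature[-L:]), set()).add(
                    gene.family_name
                )
            if L <= len(trailer) and trailer[:L].endswith(trailer_terminator):
                merged.setdefault((THREE_PRIME_U, trailer[:L]), set()).add(
                    gene.family_name
                )

    candidates = []
    for (trf_class, seq), fams in merged.items():
        naming = min(fams)
        candidates.append(
            TrfCandidate(
                name=name_trf(trf_class, fams, len(seq), mito_of[naming]),
                trf_class=trf_class,
                length=len(seq),
                sequence=seq,
                parent_families=frozenset(fams),
            )
        )
    candidates.sort(key=lambda c: (TRF_CLASSES.index(c.trf_class), c.length, c.name))
    return candidates


def write_reference(candidates, out_dir) -> None:
    """Write the tRF reference: FASTA plus a TSV index."""
    import os

    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    tio.write_fasta(
        [(c.name, c.sequence) for c in candidates],
        os.path.join(out_dir, "trf_reference.fasta"),
    )
    idx = pd.DataFrame(
        {
            "name": [c.name for c in candidates],
            "trf_class": [c.trf_class for c in candidates],
            "length": [c.length for c in candidates],
            "parent_families": [
                ";".join(sorted(c.parent_families)) for c in candidates
            ],
            "sequence": [c.sequence for c in candidates],
        }
    )
    idx.to_csv(os.path.join(out_dir, "trf_reference.tsv"), sep="\t", index=False)


def read_reference(ref_dir) -> list[TrfCandidate]:
    """Read a reference written by :func:`write_reference`."""
    import os

    import pandas as pd

    idx = pd.read_csv(os.path.join(ref_dir, "trf_reference.tsv"), sep="\t")
    return [
        TrfCandidate(
            name=row["name"],
            trf_class=row["trf_class"],
            length=int(row["length"]),
            sequence=row["sequence"],
            parent_families=frozenset(row["parent_families"].split(";")),
        )
        for _, row in idx.iterrows()
    ]
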