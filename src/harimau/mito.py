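"""Mitochondrial reference, variant notation, haplotree and haplogroup calls.

Variants are written in the compact mitochondrial community notation relative
to a 1-based reference coordinate: ``C150T`` (SNP), ``T310TC`` (insertion of
C after position 310; the reference allele is the anchor base), ``GCA513G``
(deletion of CA after position 513). The haplotree is a rooted tree whose
non-root nodes each carry one or more defining variants; a genome's
haplogroup is the tree node whose root-to-node diagnostic path best explains
the genome's variant set.

The bundled demo reference is a deterministic synthetic 16,569 bp circular
sequence (not the genuine rCRS); the bundled demo haplotree treats that
reference as the root state, with the macrohaplogroup N / R / M diagnostic
positions placed at their published coordinates and all other defining
variants being synthetic placeholders. A genuine reference and a full
haplotree can be supplied as FASTA / TSV files instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

import edlib
import numpy as np
from Bio import SeqIO

from . import InsufficientDataError, ValidationError, data_path

MT_LENGTH = 16_569
_TOKEN_RE = re.compile(r"^([ACGTN]+)(\d+)([ACGTN]+)$")
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MitoReference:
    """A circular mitochondrial reference sequence, 1-based coordinates."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        if set(self.sequence) - set("ACGTN"):
            raise ValidationError("reference alphabet must be A/C/G/T/N")

    def __len__(self):
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """1-based, circular lookup."""
        return self.sequence[(pos - 1) % len(self.sequence)]

    @classmethod
    def from_fasta(cls, path, circular: bool = True) -> "MitoReference":
        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(name=rec.id, sequence=str(rec.seq).upper(), circular=circular)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i:i + 70] + "\n")


@lru_cache(maxsize=1)
def demo_reference() -> MitoReference:
    """Deterministic synthetic 16,569 bp circular reference (seed fixed).

    Base composition loosely mimics the human mitogenome (~44% GC). This is a
    synthetic stand-in sequence, not the rCRS.
    """
    rng = np.random.default_rng(16569)
    seq = "".join(rng.choice(list("ACGT"), size=MT_LENGTH,
                             p=[0.31, 0.31, 0.13, 0.25]))
    return MitoReference(name="synthMT", sequence=seq)


@dataclass(frozen=True)
class VariantToken:
    """One variant in anchor notation: ref allele, 1-based position, alt."""

    ref: str
    pos: int
    alt: str

    def __post_init__(self):
        if not self.ref or not self.alt or self.pos < 1:
            raise ValidationError(f"malformed variant {self!r}")

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNP"
        if len(self.alt) > len(self.ref) and self.alt.startswith(self.ref):
            return "insertion"
        if len(self.ref) > len(self.alt) and self.ref.startswith(self.alt):
            return "deletion"
        return "complex"

    def __str__(self):
        return f"{self.ref}{self.pos}{self.alt}"


def parse_variant_token(text: str) -> VariantToken:
    m = _TOKEN_RE.match(text.strip().upper())
    if not m:
        raise ValidationError(f"cannot parse variant token {text!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    return VariantToken(ref=ref, pos=pos, alt=alt)


def format_variant_token(tok: VariantToken) -> str:
    return str(tok)


def _left_align(ref_seq: str, tok: VariantToken, floor: int = 1) -> VariantToken:
    """Shift an indel token left through repeats (VCF-style normalisation).

    ``floor`` is the smallest 1-based position the token may move to (used
    to keep successive tokens non-overlapping).
    """
    ref, alt, pos = tok.ref, tok.alt, tok.pos
    changed = True
    while changed:
        changed = False
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if (not ref or not alt) and pos > floor:
            prev = ref_seq[pos - 2]
            ref, alt, pos = prev + ref, prev + alt, pos - 1
            changed = True
        elif not ref or not alt:
            # cannot extend further left: re-anchor on the base to the right
            nxt = ref_seq[pos + len(ref) - 1]
            ref, alt = ref + nxt, alt + nxt
            break
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return VariantToken(ref=ref, pos=pos, alt=alt)


def apply_variants(ref: MitoReference, variants: list[VariantToken]) -> str:
    """Apply non-overlapping variants, validating reference alleles."""
    seq = ref.sequence
    pieces, cursor = [], 0
    last_end = 0
    for tok in sorted(variants, key=lambda t: t.pos):
        start = tok.pos - 1
        if start < last_end:
            raise ValidationError(f"overlapping variants near position {tok.pos}")
        if seq[start:start + len(tok.ref)] != tok.ref:
            raise ValidationError(
                f"reference mismatch at {tok.pos}: expected {tok.ref!r}, "
                f"found {seq[start:start + len(tok.ref)]!r}")
        pieces.append(seq[cursor:start])
        pieces.append(tok.alt)
        cursor = start + len(tok.ref)
        last_end = cursor
    pieces.append(seq[cursor:])
    return "".join(pieces)


def diff_to_reference(genome: str, ref: MitoReference) -> list[VariantToken]:
    """Alignment diff of a genome against the reference, as normalized tokens.

    Indels are anchored on the preceding reference base and left-aligned
    through homopolymers/repeats.
    """
    if genome == ref.sequence:
        return []
    res = edlib.align(genome, ref.sequence, task="path", mode="NW")
    ops = re.findall(r"(\d+)([=XID])", res["cigar"])
    out: list[VariantToken] = []
    gi = ri = 0  # 0-based cursors into genome / reference
    floor = 1    # leftmost position the next token may normalise to
    for count, op in ops:
        k = int(count)
        if op == "=":
            gi += k
            ri += k
        elif op == "X":
            for t in range(k):
                out.append(VariantToken(ref=ref.sequence[ri + t], pos=ri + t + 1,
                                        alt=genome[gi + t]))
            gi += k
            ri += k
            floor = ri + 1
        elif op == "I":  # bases present in genome, absent from reference
            anchor = ri  # anchor on preceding reference base
            if anchor == 0:
                raise ValidationError("insertion before position 1 unsupported")
            tok = _left_align(ref.sequence,
                              VariantToken(ref=ref.sequence[anchor - 1], pos=anchor,
                                           alt=ref.sequence[anchor - 1]
                                           + genome[gi:gi + k]),
                              floor=floor)
            out.append(tok)
            gi += k
            floor = tok.pos + len(tok.ref)
        elif op == "D":  # bases present in reference, absent from genome
            anchor = ri
            if anchor == 0:
                raise ValidationError("deletion at position 1 unsupported")
            tok = _left_align(ref.sequence,
                              VariantToken(ref=ref.sequence[anchor - 1:anchor + k],
                                           pos=anchor,
                                           alt=ref.sequence[anchor - 1]),
                              floor=floor)
            out.append(tok)
            ri += k
            floor = tok.pos + len(tok.ref)
    return sorted(out, key=lambda t: t.pos)


# ---------------------------------------------------------------------------
# haplotree


@dataclass
class HaplotreeNode:
    name: str
    parent: str | None
    variants: list[VariantToken] = field(default_factory=list)


@dataclass
class Haplotree:
    """Rooted tree of haplogroups with rCRS-style defining variants."""

    nodes: dict[str, HaplotreeNode]

    def __post_init__(self):
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValidationError(f"haplotree must have exactly one root, got {len(roots)}")
        self.root = roots[0].name
        for n in self.nodes.values():
            if n.parent is not None and n.parent not in self.nodes:
                raise ValidationError(f"unknown parent {n.parent!r} of {n.name!r}")
            if n.parent is not None and not n.variants:
                raise ValidationError(f"non-root node {n.name!r} has no defining variants")
        # cycle check
        for name in self.nodes:
            seen = set()
            while name is not None:
                if name in seen:
                    raise ValidationError("haplotree contains a cycle")
                seen.add(name)
                name = self.nodes[name].parent

    def path(self, name: str) -> list[HaplotreeNode]:
        """Root-to-node chain (root first)."""
        chain = []
        while name is not None:
            chain.append(self.nodes[name])
            name = self.nodes[name].parent
        return chain[::-1]

    def path_variants(self, name: str) -> list[VariantToken]:
        return [v for node in self.path(name) for v in node.variants]

    def depth(self, name: str) -> int:
        return len(self.path(name)) - 1

    def children(self, name: str) -> list[str]:
        return [n.name for n in self.nodes.values() if n.parent == name]

    @classmethod
    def from_tsv(cls, path) -> "Haplotree":
        """TSV columns: node, parent (empty for root), comma-separated tokens."""
        nodes = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("node\t"):
                    continue
                parts = line.split("\t")
                name, parent = parts[0], parts[1] or None
                toks = [parse_variant_token(t) for t in parts[2].split(",")] \
                    if len(parts) > 2 and parts[2] else []
                nodes[name] = HaplotreeNode(name=name, parent=parent, variants=toks)
        return cls(nodes=nodes)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node\tparent\tvariants\n")
            for n in self.nodes.values():
                toks = ",".join(str(v) for v in n.variants)
                fh.write(f"{n.name}\t{n.parent or ''}\t{toks}\n")


def demo_haplotree() -> Haplotree:
    """The bundled demo haplotree (see module docstring for provenance)."""
    return Haplotree.from_tsv(data_path("demo_haplotree.tsv"))


@dataclass
class HaplogroupCall:
    node: str
    matched: int
    missing: int
    extras: list[VariantToken]
    ambiguous: bool = False
    note: str = ""


def assign_haplogroup(variants: list[VariantToken], tree: Haplotree,
                      *, penalty: float = 1.0) -> HaplogroupCall:
    """Best-scoring haplotree node for a normalized variant set.

    Score(node) = matched path diagnostics - penalty * missing path
    diagnostics; ties resolve toward the shallower node with an ambiguity
    flag. Extras are the observed variants the winning path does not explain
    (a path diagnostic absent from the set counts as missing, mirroring
    back-mutation/masking).
    """
    if not tree.nodes:
        raise ValidationError("empty haplotree")
    have = {str(v) for v in variants}
    scored: list[tuple[float, int, str]] = []
    for name in sorted(tree.nodes):
        path = [str(v) for v in tree.path_variants(name)]
        matched = sum(1 for v in path if v in have)
        score = matched - penalty * (len(path) - matched)
        scored.append((score, tree.depth(name), name))
    best_score = max(s for s, _, _ in scored)
    tied = [(d, n) for s, d, n in scored if s == best_score]
    ambiguous = len(tied) > 1
    _, best_name = min(tied)  # shallower node wins ties
    path_set = {str(v) for v in tree.path_variants(best_name)}
    extras = [v for v in sorted(variants, key=lambda t: t.pos) if str(v) not in path_set]
    matched = sum(1 for v in path_set if v in have)
    return HaplogroupCall(node=best_name, matched=matched,
                          missing=len(path_set) - matched, extras=extras,
                          ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# APLP panel


@dataclass(frozen=True)
class APLPSite:
    position: int
    ref: str
    alt: str
    haplogroup: str
    kind: str = "SNP"  # SNP / indel / repeat


@dataclass
class APLPPanel:
    """Multiplex PCR panel of haplogroup-diagnostic sites."""

    sites: list[APLPSite]

    def __post_init__(self):
        seen = set()
        for s in self.sites:
            key = (s.position, s.kind)
            if key in seen:
                raise ValidationError(f"duplicate panel site {key}")
            seen.add(key)

    def by_position(self) -> dict[int, APLPSite]:
        return {s.position: s for s in self.sites}

    @classmethod
    def from_tsv(cls, path) -> "APLPPanel":
        sites = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("position\t"):
                    continue
                pos, ref, alt, hg, *rest = line.split("\t")
                sites.append(APLPSite(position=int(pos), ref=ref, alt=alt,
                                      haplogroup=hg,
                                      kind=rest[0] if rest else "SNP"))
        return cls(sites=sites)


def demo_panel() -> APLPPanel:
    return APLPPanel.from_tsv(data_path("demo_aplp_panel.tsv"))


def aplp_call(genotypes: dict[int, str | None], panel: APLPPanel,
              tree: Haplotree) -> str:
    """Haplogroup screen from observed alleles at panel sites.

    Returns the deepest haplotree node whose covered diagnostic panel sites
    all show the derived allele with none contradicted, descending only
    through nodes positively supported by at least one covered derived site;
    ``"N.D."`` when no non-root node is supported.
    """
    by_pos = panel.by_position()
    unknown = set(genotypes) - set(by_pos)
    if unknown:
        raise ValidationError(f"genotyped sites not in panel: {sorted(unknown)}")

    def node_sites(name: str) -> list[APLPSite]:
        return [s for s in panel.sites if s.haplogroup == name]

    def supported(name: str) -> bool:
        sites = node_sites(name)
        covered = [s for s in sites if genotypes.get(s.position) is not None]
        if not covered:
            return False
        if any(genotypes[s.position] == s.ref for s in covered):
            return False  # ancestral allele observed: contradicted
        return all(genotypes[s.position] == s.alt for s in covered)

    best = tree.root
    frontier = [tree.root]
    while frontier:
        name = frontier.pop()
        for child in tree.children(name):
            if supported(child):
                if tree.depth(child) > tree.depth(best):
                    best = child
                frontier.append(child)
    return "N.D." if best == tree.root else best
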