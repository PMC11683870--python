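"""Valence-safe molecular token strings.

Molecules are written as sequences of bracketed tokens (a SELFIES-style
robust string dialect) designed so that *every* sequence of in-vocabulary
tokens decodes to a chemically valid molecule or to the explicit empty
marker.  This is the property that lets an autoregressive generator spend
its capacity on chemistry instead of on syntax.

Dialect
-------
* Atom tokens ``[C]``, ``[=C]``, ``[#C]`` ... add an atom bonded to the
  previously placed atom with bond order 1/2/3 (the prefix is ignored for
  the first atom).  The requested order is capped by the remaining valence
  of both partners; a request that cannot form any bond ends the current
  derivation.  Element valence caps are the lowest standard valence
  (C:4, N:3, O:2, S:2, P:3, halogens:1) so that every intermediate state
  can be completed with implicit hydrogens.
* ``[Branch1]``/``[Branch2]`` open a side chain on the current atom.  The
  next 1/2 tokens are re-read as base-16 digits giving the branch length
  in tokens; the branch is derived from the current atom, reserving one
  valence unit for the main chain.  A branch on an atom with fewer than
  two free valences is skipped (tokens still consumed).
* ``[Ring1]``/``[Ring2]`` (and ``[=Ring1]``/``[=Ring2]`` for double
  bonds) bond the current atom back to an earlier atom; the following
  index token(s) give how many atoms back.  Impossible closures (no such
  atom, already bonded, no free valence) are skipped.
* ``[Break]`` terminates the molecule; a sequence may also terminate by
  hitting the configured length cap, in which case the prefix read so far
  is decoded anyway.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

BREAK_TOKEN = "[Break]"

#: lowest standard valence per supported element — any bond total below the
#: cap is completable with implicit hydrogens, which is what guarantees
#: that partial derivations sanitize.
VALENCE_CAPS = {
    "C": 4, "N": 3, "O": 2, "F": 1,
    "P": 3, "S": 2, "Cl": 1, "Br": 1, "I": 1,
}

_BOND_ORDER = {"": 1, "=": 2, "#": 3}
_ORDER_PREFIX = {1: "", 2: "=", 3: "#"}
_BOND_TYPE = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}

_ATOM_RE = re.compile(r"^\[([=#]?)(C|N|O|F|P|S|Cl|Br|I)\]$")
_BRANCH_TOKENS = {"[Branch1]": 1, "[Branch2]": 2}
_RING_TOKENS = {
    "[Ring1]": (1, 1), "[Ring2]": (2, 1),
    "[=Ring1]": (1, 2), "[=Ring2]": (2, 2),
}

#: fixed 16-token alphabet used when a token is re-read as a base-16 digit
#: (branch lengths and ring distances); any token outside it reads as 0.
INDEX_ALPHABET = [
    "[C]", "[Ring1]", "[Ring2]", "[Branch1]", "[Branch2]", "[=Ring1]",
    "[O]", "[N]", "[=N]", "[=C]", "[#C]", "[S]", "[P]", "[=O]", "[F]", "[=S]",
]
_INDEX_OF_TOKEN = {t: i for i, t in enumerate(INDEX_ALPHABET)}

DEFAULT_MAX_TOKENS = 100


class StringEncodingError(ValueError):
    """The molecule cannot be expressed in the dialect (charge, valence, ...)."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token alphabet for a generator, including the break token."""

    tokens: tuple[str, ...]
    index_of: dict[str, int] = field(init=False, repr=False, compare=False)
    break_index: int = field(init=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")
        if self.tokens.count(BREAK_TOKEN) != 1:
            raise ValueError("vocabulary must contain the break token exactly once")
        object.__setattr__(self, "index_of", {t: i for i, t in enumerate(self.tokens)})
        object.__setattr__(self, "break_index", self.index_of[BREAK_TOKEN])

    def __len__(self) -> int:
        return len(self.tokens)

    def to_indices(self, tokens: Iterable[str]) -> list[int]:
        return [self.index_of[t] for t in tokens]

    def to_tokens(self, indices: Iterable[int]) -> list[str]:
        return [self.tokens[i] for i in indices]

    def to_json(self) -> str:
        return json.dumps({"dialect": "molminer-1", "tokens": list(self.tokens)})

    @classmethod
    def from_json(cls, text: str) -> "TokenVocabulary":
        payload = json.loads(text)
        return cls(tuple(payload["tokens"]))


@dataclass
class TokenSequence:
    """Indices into a vocabulary; ``terminated`` marks break-or-cap ending."""

    indices: list[int]
    terminated: bool = True
    terminated_by_cap: bool = False

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class MoleculeRecord:
    smiles_canonical: str
    selfies: str
    source: str = "generated"  # corpus | generated
    scores: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# encoding


def _prepared_mol(smiles: str) -> Chem.RWMol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StringEncodingError(f"unparseable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise StringEncodingError(f"multi-fragment molecules unsupported: {smiles!r}")
    rw = Chem.RWMol(mol)
    Chem.Kekulize(rw, clearAromaticFlags=True)
    for atom in rw.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in VALENCE_CAPS:
            raise StringEncodingError(f"unsupported element {sym} in {smiles!r}")
        if atom.GetFormalCharge() != 0 or atom.GetNumRadicalElectrons() != 0:
            raise StringEncodingError(f"charged/radical atoms unsupported: {smiles!r}")
        atom.SetIsotope(0)
        total = int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
        if total > VALENCE_CAPS[sym]:
            raise StringEncodingError(
                f"atom {sym} exceeds dialect valence cap in {smiles!r}"
            )
    for bond in rw.GetBonds():
        if int(bond.GetBondTypeAsDouble()) not in (1, 2, 3):
            raise StringEncodingError(f"unsupported bond order in {smiles!r}")
    return rw


def _index_tokens(value: int, width: int) -> list[str]:
    digits = []
    for _ in range(width):
        digits.append(INDEX_ALPHABET[value % 16])
        value //= 16
    if value:
        raise StringEncodingError("branch/ring reference out of range")
    return digits[::-1]


def encode(smiles: str) -> list[str]:
    """Encode a SMILES string into dialect tokens (break token not included)."""
    mol = _prepared_mol(smiles)
    pos: dict[int, int] = {}
    emitted_rings: set[frozenset] = set()

    def subtree(v: int, parent: int | None, order: int) -> list[str]:
        pos[v] = len(pos)
        prefix = "" if parent is None else _ORDER_PREFIX[order]
        toks = [f"[{prefix}{mol.GetAtomWithIdx(v).GetSymbol()}]"]
        neighbors = sorted(n.GetIdx() for n in mol.GetAtomWithIdx(v).GetNeighbors())
        # ring closures: edges to atoms visited before v
        for u in neighbors:
            key = frozenset((u, v))
            if u in pos and u != parent and key not in emitted_rings:
                emitted_rings.add(key)
                bond = mol.GetBondBetweenAtoms(u, v)
                b = int(bond.GetBondTypeAsDouble())
                if b == 3:
                    raise StringEncodingError("triple-bond ring closures unsupported")
                q = pos[v] - pos[u] - 1
                mark = "=" if b == 2 else ""
                if q < 16:
                    toks += [f"[{mark}Ring1]"] + _index_tokens(q, 1)
                else:
                    toks += [f"[{mark}Ring2]"] + _index_tokens(q, 2)
        for u in neighbors:
            if u in pos:
                continue
            bond = mol.GetBondBetweenAtoms(u, v)
            child = subtree(u, v, int(bond.GetBondTypeAsDouble()))
            if any(n.GetIdx() not in pos for n in mol.GetAtomWithIdx(v).GetNeighbors()):
                length = len(child)
                if length <= 16:
                    toks += ["[Branch1]"] + _index_tokens(length - 1, 1) + child
                elif length <= 256:
                    toks += ["[Branch2]"] + _index_tokens(length - 1, 2) + child
                else:
                    raise StringEncodingError("branch too long for dialect")
            else:
                toks += child
        return toks

    return subtree(0, None, 1)


# ---------------------------------------------------------------------------
# decoding


class _Stop(Exception):
    pass


class _Builder:
    def __init__(self) -> None:
        self.mol = Chem.RWMol()
        self.order: list[int] = []
        self.pos: dict[int, int] = {}
        self.used: dict[int, int] = {}

    def free(self, idx: int) -> int:
        return VALENCE_CAPS[self.mol.GetAtomWithIdx(idx).GetSymbol()] - self.used[idx]

    def add_atom(self, symbol: str) -> int:
        idx = self.mol.AddAtom(Chem.Atom(symbol))
        self.pos[idx] = len(self.order)
        self.order.append(idx)
        self.used[idx] = 0
        return idx

    def add_bond(self, a: int, b: int, order: int) -> None:
        self.mol.AddBond(a, b, _BOND_TYPE[order])
        self.used[a] += order
        self.used[b] += order


def _derive(tokens: Sequence[str], b: _Builder, prev: int | None, cap_first: int | None) -> None:
    i = 0
    first_bond_pending = cap_first is not None
    while i < len(tokens):
        tok = tokens[i]
        i += 1
        if tok == BREAK_TOKEN:
            raise _Stop
        m = _ATOM_RE.match(tok)
        if m:
            want = _BOND_ORDER[m.group(1)]
            sym = m.group(2)
            if prev is None:
                prev = b.add_atom(sym)
                continue
            avail = b.free(prev)
            if first_bond_pending:
                avail = min(avail, cap_first)
            order = min(want, avail, VALENCE_CAPS[sym])
            if order < 1:
                return  # attachment point saturated: end this derivation
            new = b.add_atom(sym)
            b.add_bond(prev, new, order)
            first_bond_pending = False
            prev = new
            continue
        if tok in _BRANCH_TOKENS:
            width = _BRANCH_TOKENS[tok]
            if i + width > len(tokens):
                return
            q = 0
            for d in tokens[i:i + width]:
                q = q * 16 + _INDEX_OF_TOKEN.get(d, 0)
            i += width
            if prev is None or b.free(prev) < 2:
                # unusable branch: skip only the symbol and its index so the
                # would-be branch body still derives as main chain
                continue
            length = q + 1
            branch = tokens[i:i + length]
            i += length
            _derive(branch, b, prev, cap_first=b.free(prev) - 1)
            continue
        if tok in _RING_TOKENS:
            width, want = _RING_TOKENS[tok]
            if i + width > len(tokens):
                return
            q = 0
            for d in tokens[i:i + width]:
                q = q * 16 + _INDEX_OF_TOKEN.get(d, 0)
            i += width
            if prev is None:
                continue
            tpos = b.pos[prev] - (q + 1)
            if tpos < 0:
                continue
            target = b.order[tpos]
            if target == prev or b.mol.GetBondBetweenAtoms(prev, target) is not None:
                continue
            avail = b.free(prev)
            if first_bond_pending:
                avail = min(avail, cap_first)
            order = min(want, avail, b.free(target))
            if order >= 1:
                b.add_bond(prev, target, order)
                first_bond_pending = False
            continue
        raise ValueError(f"unknown token {tok!r}")


def decode(tokens: Sequence[str]) -> str | None:
    """Decode dialect tokens to a canonical SMILES, or ``None`` when empty.

    Never raises for sequences drawn from the dialect alphabet — this is
    the contract that makes random generator output safe to consume.
    """
    b = _Builder()
    try:
        _derive(list(tokens), b, None, None)
    except _Stop:
        pass
    if b.mol.GetNumAtoms() == 0:
        return None
    try:
        mol = b.mol.GetMol()
        Chem.SanitizeMol(mol)
        smiles = Chem.MolToSmiles(mol)
        if Chem.MolFromSmiles(smiles) is None:  # pragma: no cover - safety net
            return None
        return smiles
    except Exception:  # pragma: no cover - safety net
        return None


# ---------------------------------------------------------------------------
# public helpers


def canonical_identity(smiles: str) -> str:
    """Canonical isomeric SMILES used as molecule identity throughout."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def tokens_to_string(tokens: Iterable[str]) -> str:
    return "".join(tokens)


def string_to_tokens(text: str) -> list[str]:
    toks = re.findall(r"\[[^\]]*\]", text)
    if "".join(toks) != text:
        raise ValueError(f"malformed token string: {text!r}")
    return toks


def build_vocabulary(corpus: Sequence[str]) -> TokenVocabulary:
    """Collect the token alphabet of a corpus (sorted, plus the break token).

    Raises with the offending line number on unparseable/unsupported input.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    seen: set[str] = set()
    for lineno, smiles in enumerate(corpus, start=1):
        try:
            seen.update(encode(smiles))
        except StringEncodingError as exc:
            raise StringEncodingError(f"line {lineno}: {exc}") from exc
    return TokenVocabulary(tuple(sorted(seen)) + (BREAK_TOKEN,))


def encode_sequence(smiles: str, vocab: TokenVocabulary,
                    max_tokens: int = DEFAULT_MAX_TOKENS) -> TokenSequence:
    """Encode a molecule as vocabulary indices, break-terminated."""
    toks = encode(smiles)
    if len(toks) + 1 > max_tokens:
        raise StringEncodingError(f"molecule exceeds {max_tokens}-token cap: {smiles!r}")
    return TokenSequence(vocab.to_indices(toks) + [vocab.break_index])


def decode_sequence(seq: TokenSequence | Sequence[int],
                    vocab: TokenVocabulary) -> MoleculeRecord | None:
    """Decode vocabulary indices; returns ``None`` for the empty molecule."""
    indices = seq.indices if isinstance(seq, TokenSequence) else list(seq)
    toks = vocab.to_tokens(indices)
    smiles = decode(toks)
    if smiles is None:
        return None
    stop = toks.index(BREAK_TOKEN) if BREAK_TOKEN in toks else len(toks)
    return MoleculeRecord(smiles_canonical=smiles,
                          selfies=tokens_to_string(toks[:stop]))


def read_smiles_file(path) -> list[str]:
    """One molecule per line; optional tab-separated name column ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0].split()[0])
    return out


def write_smiles_file(path, smiles: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for s in smiles:
            fh.write(s + "\n")


def read_sdf(path) -> list[Chem.Mol]:
    """Read molecules (with any 3D coordinates) from an SDF file."""
    return [m for m in Chem.SDMolSupplier(str(path), removeHs=False)
            if m is not None]


def write_sdf(path, mols: Iterable[Chem.Mol]) -> None:
    writer = Chem.SDWriter(str(path))
    for mol in mols:
        writer.write(mol)
    writer.close()
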