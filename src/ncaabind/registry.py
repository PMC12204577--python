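"""Token -> SMILES registry for canonical and non-canonical amino acids.

Each residue token (a one-letter canonical code, or a multi-character
non-canonical token such as ``V_OTH`` or ``Phg``) is bound to the SMILES of
the corresponding *free* amino acid in neutral form.  The 20 canonical
L-amino acids are built in; non-canonical entries are supplied by the user
from a TSV or JSON file and validated with RDKit at load time.

SMILES are canonicalized on load so string equality of stored SMILES is a
well-defined structure comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from rdkit import Chem
from rdkit import RDLogger

from .errors import RegistryError, TokenResolutionError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")

#: Free neutral L-amino acids (glycine achiral), one-letter code -> SMILES.
CANONICAL_SMILES: dict[str, str] = {
    "A": "C[C@@H](N)C(=O)O",
    "R": "N[C@@H](CCCNC(=N)N)C(=O)O",
    "N": "NC(=O)C[C@H](N)C(=O)O",
    "D": "N[C@@H](CC(=O)O)C(=O)O",
    "C": "N[C@@H](CS)C(=O)O",
    "E": "N[C@@H](CCC(=O)O)C(=O)O",
    "Q": "NC(=O)CC[C@H](N)C(=O)O",
    "G": "NCC(=O)O",
    "H": "N[C@@H](Cc1c[nH]cn1)C(=O)O",
    "I": "CC[C@H](C)[C@H](N)C(=O)O",
    "L": "CC(C)C[C@H](N)C(=O)O",
    "K": "NCCCC[C@H](N)C(=O)O",
    "M": "CSCC[C@H](N)C(=O)O",
    "F": "N[C@@H](Cc1ccccc1)C(=O)O",
    "P": "O=C(O)[C@@H]1CCCN1",
    "S": "N[C@@H](CO)C(=O)O",
    "T": "C[C@@H](O)[C@H](N)C(=O)O",
    "W": "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O",
    "Y": "N[C@@H](Cc1ccc(O)cc1)C(=O)O",
    "V": "CC(C)[C@H](N)C(=O)O",
}

CANONICAL_TOKENS = frozenset(CANONICAL_SMILES)


def canonicalize_smiles(smiles: str, context: str = "") -> str:
    """Parse *smiles* with RDKit and return its canonical form.

    Raises :class:`RegistryError` naming *context* when the string does not
    parse to a valid molecule.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise RegistryError(f"invalid SMILES {smiles!r} for {context or 'entry'}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class TokenChemEntry:
    """One token bound to the structure of its free amino acid."""

    token_id: str
    smiles: str
    display_name: str | None = None
    source: str = "user"

    def mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # pragma: no cover - entries are validated on creation
            raise RegistryError(f"stored SMILES for {self.token_id!r} no longer parses")
        return mol


@dataclass
class ChemRegistry:
    """Mapping of token ids to chemistry, with alias indirection.

    Resolution is total over ``entries | aliases`` and fails loudly on
    anything else — an unknown token is the user's signal to extend the
    registry, never a silent fallback to a canonical residue.
    """

    entries: dict[str, TokenChemEntry] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, token_id: str) -> bool:
        return token_id in self.entries or token_id in self.aliases

    def token_ids(self) -> list[str]:
        return sorted(self.entries)

    def add(self, entry: TokenChemEntry, *, override: bool = False) -> None:
        if entry.token_id in self.entries and not override:
            raise RegistryError(f"duplicate token_id {entry.token_id!r}")
        canonical = canonicalize_smiles(entry.smiles, context=f"token {entry.token_id!r}")
        self.entries[entry.token_id] = replace(entry, smiles=canonical)

    def add_alias(self, alias: str, target: str) -> None:
        if target not in self.entries:
            raise RegistryError(f"alias {alias!r} targets unknown token {target!r}")
        self.aliases[alias] = target

    def resolve(self, token_id: str) -> TokenChemEntry:
        if token_id in self.entries:
            return self.entries[token_id]
        if token_id in self.aliases:
            return self.entries[self.aliases[token_id]]
        raise TokenResolutionError(token_id)

    def resolve_id(self, token_id: str) -> str:
        """Collapse an alias to its canonical token id."""
        return self.resolve(token_id).token_id

    def copy(self) -> "ChemRegistry":
        return ChemRegistry(entries=dict(self.entries), aliases=dict(self.aliases))


def builtin_canonical() -> ChemRegistry:
    """Registry holding exactly the 20 canonical amino acids."""
    reg = ChemRegistry()
    for letter, smi in CANONICAL_SMILES.items():
        reg.add(TokenChemEntry(token_id=letter, smiles=smi, source="builtin"))
    return reg


def _iter_file_entries(path: Path) -> Iterable[dict]:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else []
        if not isinstance(data, list):
            raise RegistryError(f"{path}: JSON registry must be an array of objects")
        yield from data
        return
    # TSV: header line token_id<TAB>smiles[<TAB>display_name[<TAB>source]]
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        return
    header = [h.strip() for h in lines[0].split("\t")]
    if "token_id" not in header or "smiles" not in header:
        raise RegistryError(f"{path}: TSV header must contain token_id and smiles")
    for ln in lines[1:]:
        cells = ln.split("\t")
        row = {h: cells[i].strip() if i < len(cells) else "" for i, h in enumerate(header)}
        yield row


def load_registry(path: str | Path, base: ChemRegistry | None = None) -> ChemRegistry:
    """Extend *base* (default: canonical 20) with entries from a TSV/JSON file.

    Every SMILES is validated at load; an invalid SMILES or a token_id that
    appears twice within the file raises :class:`RegistryError` naming the
    token.  File entries override base entries with the same id.
    """
    path = Path(path)
    if not path.exists():
        raise RegistryError(f"registry file not found: {path}")
    reg = (base or builtin_canonical()).copy()
    seen_in_file: set[str] = set()
    pending_aliases: list[tuple[str, str]] = []
    for row in _iter_file_entries(path):
        token_id = str(row.get("token_id", "")).strip()
        if not token_id:
            raise RegistryError(f"{path}: entry without token_id")
        if "alias_of" in row and row["alias_of"]:
            pending_aliases.append((token_id, str(row["alias_of"]).strip()))
            continue
        if token_id in seen_in_file:
            raise RegistryError(f"{path}: duplicate token_id {token_id!r} within file")
        seen_in_file.add(token_id)
        smiles = str(row.get("smiles", "")).strip()
        if not smiles:
            raise RegistryError(f"{path}: token {token_id!r} has no SMILES")
        entry = TokenChemEntry(
            token_id=token_id,
            smiles=smiles,
            display_name=str(row["display_name"]).strip() or None
            if row.get("display_name")
            else None,
            source=str(row.get("source") or path.name),
        )
        reg.add(entry, override=True)
    for alias, target in pending_aliases:
        reg.add_alias(alias, target)
    logger.info("loaded registry %s: %d entries, %d aliases", path, len(reg), len(reg.aliases))
    return reg


def write_registry(reg: ChemRegistry, path: str | Path) -> None:
    """Write the registry as the TSV interchange format."""
    path = Path(path)
    lines = ["token_id\tsmiles\tdisplay_name\tsource\talias_of"]
    for token_id in sorted(reg.entries):
        e = reg.entries[token_id]
        lines.append(f"{e.token_id}\t{e.smiles}\t{e.display_name or ''}\t{e.source}\t")
    for alias, target in sorted(reg.aliases.items()):
        lines.append(f"{alias}\t\t\t\t{target}")
    path.write_text("\n".join(lines) + "\n")
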