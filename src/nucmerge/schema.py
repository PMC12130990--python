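"""Harmonization of model cell-type vocabularies as a label tree.

Two pretrained nuclei-classification models rarely share a vocabulary: a
model trained on MoNuSAC predicts epithelial / lymphocyte / neutrophil /
macrophage, while a model trained on PanNuke predicts neoplastic and
non-neoplastic epithelial / connective / inflammatory / dead. To decide
whether two spatially-overlapping predictions agree on type, each raw label
is mapped into a tree of categories rooted at ``cell``, arranged so a child
node is always a refinement of its parent. Two labels *match* when they
share the same **match-level** node (by default the depth-1 ancestor, e.g.
both ``lymphocyte`` and ``inflammatory`` match at ``inflammatory``). The
**output category** of a merged pair is the more specific of the two nodes,
so the merged output can report ``lymphocyte`` even though only one model
can name it.

The shipped default schema encodes the MoNuSAC/PanNuke pairing; any other
pairing is supplied as a YAML or JSON config file (see ``default_schema_dict``
for the exact document structure).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import yaml

from .errors import SchemaError

ROOT = "cell"

#: Vocabulary of the HoVer-Net model pretrained on MoNuSAC.
MONUSAC_LABELS = frozenset(
    {"epithelial", "lymphocyte", "neutrophil", "macrophage"}
)
#: Vocabulary of the HoVer-Net model pretrained on PanNuke.
PANNUKE_LABELS = frozenset(
    {
        "neoplastic epithelial",
        "non-neoplastic epithelial",
        "connective",
        "inflammatory",
        "dead",
    }
)


def default_schema_dict() -> dict[str, Any]:
    """The shipped default schema as a plain config document.

    The same structure is accepted from YAML/JSON files: ``tree`` is a
    nested mapping of category nodes under the root, ``match_level``
    optionally overrides the ancestor at which cross-model equality is
    tested (default: the depth-1 ancestor of each node), and each entry of
    ``models`` maps a model id to its raw-label -> node assignment plus an
    optional declared ``vocabulary`` that the label map must cover.
    """
    return {
        "tree": {
            ROOT: {
                "epithelial": {
                    "neoplastic epithelial": {},
                    "non-neoplastic epithelial": {},
                },
                "inflammatory": {
                    "lymphocyte": {},
                    "neutrophil": {},
                    "macrophage": {},
                },
                "connective": {},
                "dead": {},
            }
        },
        "models": {
            "monusac": {
                "vocabulary": sorted(MONUSAC_LABELS),
                "labels": {
                    "epithelial": "epithelial",
                    "lymphocyte": "lymphocyte",
                    "neutrophil": "neutrophil",
                    "macrophage": "macrophage",
                },
            },
            "pannuke": {
                "vocabulary": sorted(PANNUKE_LABELS),
                "labels": {
                    "neoplastic epithelial": "neoplastic epithelial",
                    "non-neoplastic epithelial": "non-neoplastic epithelial",
                    "connective": "connective",
                    "inflammatory": "inflammatory",
                    "dead": "dead",
                },
            },
        },
    }


class TypeSchema:
    """Tree-structured mapping of raw model labels to harmonized categories."""

    def __init__(
        self,
        parent: dict[str, str | None],
        model_map: dict[str, dict[str, str]],
        match_level: dict[str, str],
        root: str = ROOT,
    ) -> None:
        self.root = root
        self.parent = parent
        self.model_map = model_map
        self.match_level = match_level
        self._children: dict[str, list[str]] = {n: [] for n in parent}
        for node, par in parent.items():
            if par is not None:
                self._children[par].append(node)
        self._depth: dict[str, int] = {}
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "TypeSchema":
        tree = doc.get("tree")
        if not isinstance(tree, dict) or len(tree) != 1:
            raise SchemaError("schema 'tree' must have exactly one root node")
        root = next(iter(tree))
        parent: dict[str, str | None] = {root: None}

        def walk(node: str, sub: Any) -> None:
            if not isinstance(sub, dict):
                raise SchemaError(f"tree node {node!r} must map to a mapping")
            for child, grand in sub.items():
                if child in parent:
                    raise SchemaError(
                        f"node {child!r} appears more than once in the tree"
                    )
                parent[child] = node
                walk(child, grand)

        walk(root, tree[root])

        model_map: dict[str, dict[str, str]] = {}
        for model_id, section in (doc.get("models") or {}).items():
            labels = section.get("labels")
            if not isinstance(labels, dict) or not labels:
                raise SchemaError(f"model {model_id!r} declares no labels")
            vocab = section.get("vocabulary")
            if vocab is not None:
                missing = set(vocab) - set(labels)
                if missing:
                    raise SchemaError(
                        f"model {model_id!r}: vocabulary labels "
                        f"{sorted(missing)} have no node mapping"
                    )
            model_map[model_id] = dict(labels)
        if not model_map:
            raise SchemaError("schema declares no models")

        match_level = dict(doc.get("match_level") or {})
        return cls(parent, model_map, match_level, root=root)

    @classmethod
    def default(cls) -> "TypeSchema":
        return cls.from_dict(default_schema_dict())

    def _validate(self) -> None:
        # cycle / orphan check while computing depths
        for node in self.parent:
            depth, cur = 0, node
            seen = {node}
            while self.parent[cur] is not None:
                cur = self.parent[cur]
                if cur not in self.parent:
                    raise SchemaError(f"node {node!r} has unknown ancestor {cur!r}")
                if cur in seen:
                    raise SchemaError(f"cycle in tree through {cur!r}")
                seen.add(cur)
                depth += 1
            if cur != self.root:
                raise SchemaError(f"node {node!r} does not descend from root")
            self._depth[node] = depth
        for model_id, labels in self.model_map.items():
            for raw, node in labels.items():
                if node not in self.parent:
                    raise SchemaError(
                        f"model {model_id!r}: label {raw!r} mapped to "
                        f"unknown node {node!r}"
                    )
        # fill default match levels: the depth-1 ancestor (or self at depth<=1)
        for node in self.parent:
            if node == self.root:
                continue
            lvl = self.match_level.get(node)
            if lvl is None:
                lvl = node
                while self._depth[lvl] > 1:
                    lvl = self.parent[lvl]  # type: ignore[assignment]
                self.match_level[node] = lvl
            elif not self.is_ancestor_or_self(self.match_level[node], node):
                raise SchemaError(
                    f"match level {self.match_level[node]!r} is not an "
                    f"ancestor of {node!r}"
                )

    # -- queries ----------------------------------------------------------

    def depth(self, node: str) -> int:
        return self._depth[node]

    def is_ancestor_or_self(self, a: str, b: str) -> bool:
        cur: str | None = b
        while cur is not None:
            if cur == a:
                return True
            cur = self.parent[cur]
        return False

    def node_of(self, model_id: str, raw_label: str) -> str:
        try:
            labels = self.model_map[model_id]
        except KeyError:
            raise SchemaError(f"model {model_id!r} not declared in schema")
        try:
            return labels[raw_label]
        except KeyError:
            raise SchemaError(
                f"label {raw_label!r} of model {model_id!r} is not mapped"
            )

    def match_node(self, model_id: str, raw_label: str) -> str:
        return self.match_level[self.node_of(model_id, raw_label)]

    def types_match(
        self, label_a: str, model_a: str, label_b: str, model_b: str
    ) -> bool:
        """True iff the two raw labels share the same match-level node."""
        return self.match_node(model_a, label_a) == self.match_node(
            model_b, label_b
        )

    def output_category(
        self, label_a: str, model_a: str, label_b: str, model_b: str
    ) -> str:
        """Most specific node of a matching pair.

        When one node lies on the other's lineage the descendant wins;
        otherwise (two siblings under the same match level) the deeper node
        wins, with the second argument preferred on equal depth.
        """
        from .errors import ContractError

        if not self.types_match(label_a, model_a, label_b, model_b):
            raise ContractError(
                f"output_category called on non-matching labels "
                f"{label_a!r} ({model_a}) vs {label_b!r} ({model_b})"
            )
        na = self.node_of(model_a, label_a)
        nb = self.node_of(model_b, label_b)
        if self.is_ancestor_or_self(na, nb):
            return nb
        if self.is_ancestor_or_self(nb, na):
            return na
        return nb if self._depth[nb] >= self._depth[na] else na

    def categories(self) -> list[str]:
        """All non-root nodes in deterministic preorder."""
        out: list[str] = []

        def walk(node: str) -> None:
            for child in self._children[node]:
                out.append(child)
                walk(child)

        walk(self.root)
        return out


def load_schema(path: str | Path | None = None) -> TypeSchema:
    """Load a schema config (YAML or JSON); the shipped default when omitted."""
    if path is None:
        return TypeSchema.default()
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: schema config must be a mapping")
    return TypeSchema.from_dict(doc)
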