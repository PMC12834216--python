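"""Render a disconnectivity tree (JSON export) as the classic 'willow' plot.

Usage: python scripts/plot_tree.py tree.json [-o tree.png] [--window 30]

Vertical lines drop from each merge lid to the next merge or to a leaf's
energy; leaves are coloured by packing motif when the export carries one.
"""
from __future__ import annotations

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

MOTIF_COLORS = {
    "H": "tab:blue", "SH": "tab:orange", "beta": "tab:green",
    "gamma": "tab:red", "other": "0.6",
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("tree", type=Path)
    ap.add_argument("-o", "--out", type=Path, default=Path("tree.png"))
    ap.add_argument("--window", type=float, default=None,
                    help="drop leaves above global minimum + window (kJ/mol)")
    args = ap.parse_args()

    data = json.loads(args.tree.read_text())
    nodes = {n["node_id"]: n for n in data["nodes"]}
    motifs = data.get("motifs", {})
    leaves = [n for n in nodes.values() if n["minimum_id"] is not None]
    e_min = min(n["energy"] for n in leaves)
    keep = {
        n["node_id"]
        for n in leaves
        if args.window is None or n["energy"] <= e_min + args.window
    }

    def visible(nid):
        n = nodes[nid]
        if n["minimum_id"] is not None:
            return nid in keep
        return any(visible(c) for c in n["children"])

    fig, ax = plt.subplots(figsize=(8, 6))
    x_next = [0.0]

    def layout(nid, top):
        """Returns x position; draws the subtree hanging below `top`."""
        n = nodes[nid]
        if n["minimum_id"] is not None:
            x = x_next[0]
            x_next[0] += 1.0
            color = MOTIF_COLORS.get(motifs.get(str(n["minimum_id"]), "other"), "0.6")
            ax.plot([x, x], [top, n["energy"]], color=color, lw=1.0)
            ax.plot([x], [n["energy"]], marker="o", ms=3, color=color)
            return x
        xs = [layout(c, n["lid"]) for c in n["children"] if visible(c)]
        x = sum(xs) / len(xs)
        ax.plot([min(xs), max(xs)], [n["lid"], n["lid"]], color="k", lw=1.0)
        ax.plot([x, x], [top, n["lid"]], color="k", lw=1.0)
        return x

    roots = [nid for nid, n in nodes.items() if n["parent"] is None and visible(nid)]
    for r in roots:
        top = nodes[r]["lid"] if nodes[r]["lid"] is not None else nodes[r]["energy"]
        layout(r, top + 1.0)
    ax.set_ylabel("lattice energy / lid  (kJ/mol)")
    ax.set_xticks([])
    for motif, color in MOTIF_COLORS.items():
        ax.plot([], [], color=color, label=motif)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
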