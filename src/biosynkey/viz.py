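"""Count-distribution "QR code" heatmaps and 2-D similarity embeddings.

A QR matrix summarises a molecule set: one column per substructure key, one
row per count value 0..11, plus an overflow row pooling counts of 12 and
above.  Each cell holds the fraction of molecules showing exactly that
count, so every column sums to one.  Rendered with keys ordered (and
colour-annotated) by pathway block and the overflow row on its own colour
scale, the heatmap gives an at-a-glance picture of a dataset's biosynthetic
make-up.  Embeddings (t-SNE, UMAP) consume 1 − similarity as a precomputed
distance matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .keyset import KeyRegistry
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = ["QRMatrix", "Embedding", "qr_matrix", "render_qr", "embed"]

COUNT_CAP = 11  # exact rows 0..11; counts above pool into the overflow row

PATHWAY_COLOURS = {
    "shikimate": "#7b3294",
    "acetate": "#e66101",
    "terpenoid": "#1b9e77",
    "carbohydrate": "#d01c8b",
    "amino-acid": "#2c7bb6",
    "none": "#888888",
}


@dataclass(frozen=True)
class QRMatrix:
    """Per-key distribution of count values over a molecule set.

    ``values`` is indexed by count value 0..11 plus the ``">11"`` overflow
    row; columns are key names in registry order; cells are molecule
    fractions, so each column sums to 1.
    """

    values: pd.DataFrame
    n_molecules: int

    @property
    def overflow_row(self) -> pd.Series:
        return self.values.loc[">11"]


def qr_matrix(table: pd.DataFrame) -> QRMatrix:
    """Distribution matrix of count values per key.

    ``table`` is a fingerprint table (a ``coverage`` column, if present, is
    ignored).  Counts of 12 and above land in the overflow row.
    """
    counts = table.drop(columns="coverage", errors="ignore")
    if counts.empty:
        raise ValueError("empty fingerprint table")
    n = len(counts)
    rows: dict[object, np.ndarray] = {}
    arr = counts.to_numpy()
    for value in range(COUNT_CAP + 1):
        rows[value] = (arr == value).mean(axis=0)
    rows[">11"] = (arr > COUNT_CAP).mean(axis=0)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=counts.columns)
    return QRMatrix(values=frame, n_molecules=n)


def render_qr(
    matrix: QRMatrix,
    out,
    registry: KeyRegistry | None = None,
    show_zero_row: bool = False,
    dpi: int = 150,
) -> None:
    """Render a QR matrix as a heatmap (PNG/SVG by file extension).

    Count rows 1..11 (and optionally 0) share one colour scale; the
    overflow row is drawn above them on its own scale so rare high counts
    stay distinguishable.  When a registry is given, key labels are
    coloured by pathway.
    """
    body_rows = list(range(0 if show_zero_row else 1, COUNT_CAP + 1))
    body = matrix.values.loc[body_rows]
    overflow = matrix.values.loc[[">11"]]
    n_keys = matrix.values.shape[1]

    fig, (ax_over, ax_body) = plt.subplots(
        2,
        1,
        figsize=(max(6.0, 0.32 * n_keys), 5.0),
        gridspec_kw={"height_ratios": [1, len(body_rows)]},
        sharex=True,
    )
    im_over = ax_over.imshow(
        overflow.to_numpy(), aspect="auto", cmap="Reds", vmin=0.0
    )
    ax_over.set_yticks([0], [">11"])
    im_body = ax_body.imshow(
        body.to_numpy()[::-1], aspect="auto", cmap="Blues", vmin=0.0
    )
    ax_body.set_yticks(range(len(body_rows)), [str(r) for r in body_rows[::-1]])
    ax_body.set_xticks(range(n_keys), list(matrix.values.columns), rotation=90, fontsize=6)
    ax_body.set_ylabel("substructure count")
    if registry is not None:
        for tick in ax_body.get_xticklabels():
            name = tick.get_text()
            if name in registry:
                tick.set_color(PATHWAY_COLOURS[registry[name].pathway])
    fig.colorbar(im_body, ax=ax_body, fraction=0.025, label="fraction of molecules")
    fig.colorbar(im_over, ax=ax_over, fraction=0.15)
    fig.suptitle(f"count distribution over {matrix.n_molecules} molecules")
    fig.tight_layout()
    fig.savefig(out, dpi=dpi)
    plt.close(fig)


@dataclass(frozen=True)
class Embedding:
    """2-D coordinates of a molecule set plus the parameters that made them."""

    ids: tuple[str, ...]
    coordinates: np.ndarray
    method: str
    parameters: dict = field(default_factory=dict)
    colour_labels: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.coordinates, index=list(self.ids), columns=["x", "y"])
        frame["label"] = [self.colour_labels.get(i, "") for i in self.ids]
        return frame


def embed(
    matrix: SimilarityMatrix,
    method: str = "tsne",
    seed: int = 0,
    perplexity: float = 50.0,
    max_iter: int = 2000,
    labels: dict[str, set[str]] | None = None,
) -> Embedding:
    """Embed molecules in 2-D from their similarity matrix.

    The embedding runs on the distance matrix 1 − similarity in
    precomputed-distance mode.  t-SNE uses perplexity 50 and 2000
    iterations by default (perplexity is reduced with a warning when the
    set is too small for it); UMAP runs with its default settings.  When a
    ``labels`` mapping is given, compounds with exactly one class get that
    class as their colour label; multi-class compounds are embedded but
    left uncoloured.
    """
    values = matrix.values
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 molecules to embed")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    distance = matrix.to_distance()
    np.fill_diagonal(distance, 0.0)

    if method == "tsne":
        from sklearn.manifold import TSNE

        max_perplexity = (n - 1) / 3
        if perplexity >= max_perplexity:
            new_perplexity = max(1.0, max_perplexity - 1e-6)
            logger.warning(
                "perplexity %.1f too large for n=%d; reduced to %.2f",
                perplexity,
                n,
                new_perplexity,
            )
            perplexity = new_perplexity
        model = TSNE(
            n_components=2,
            metric="precomputed",
            init="random",
            perplexity=perplexity,
            max_iter=max_iter,
            random_state=seed,
        )
        coords = model.fit_transform(distance)
        params = {"perplexity": perplexity, "max_iter": max_iter, "seed": seed}
    elif method == "umap":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # umap warns about precomputed metric
            from umap import UMAP

            model = UMAP(n_components=2, metric="precomputed", random_state=seed)
            coords = model.fit_transform(distance)
        params = {"defaults": True, "seed": seed}
    else:
        raise ValueError(f"method must be 'tsne' or 'umap', got {method!r}")

    colour: dict[str, str] = {}
    if labels:
        for mol_id in matrix.ids:
            assigned = labels.get(mol_id, set())
            if len(assigned) == 1:
                colour[mol_id] = next(iter(assigned))
    return Embedding(
        ids=matrix.ids,
        coordinates=np.asarray(coords, dtype=float),
        method=method,
        parameters=params,
        colour_labels=colour,
    )
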