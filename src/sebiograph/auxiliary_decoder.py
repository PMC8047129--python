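"""Graph-autoencoder reconstruction constraint.

A one-layer decoder convolution maps the encoder output H to decoded
embeddings Z = GNN_dec(A, H); the constraint penalizes the squared
Frobenius distance between the adjacency and the Gram matrix of the decoded
embeddings, ‖A − ZZᵀ‖²_F.  No link function is applied to the Gram matrix
by default; ``decoder_link="sigmoid"`` gives the standard graph-autoencoder
variant.  The loss regularizes embedding quality on every graph in the
batch, auxiliary and target alike.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .config import RunConfig
from .graph_io import BioGraph
from .nn import ModelParams

__all__ = ["gram_reconstruction_error", "decode", "reconstruction_loss"]


def gram_reconstruction_error(
    adjacency: np.ndarray | Tensor,
    z: Tensor,
    reduction: str = "sum",
    link: str = "linear",
) -> Tensor:
    """‖A − ZZᵀ‖²_F (entry sum, or per-entry mean with reduction="mean")."""
    a = adjacency if isinstance(adjacency, Tensor) else Tensor(adjacency)
    if z.shape[0] != a.shape[0]:
        raise ValueError(
            f"decoder rows {z.shape[0]} do not match adjacency {a.shape[0]}"
        )
    gram = z @ z.T
    if link == "sigmoid":
        gram = gram.sigmoid()
    elif link != "linear":
        raise ValueError(f"unknown decoder_link {link!r}")
    resid = (a - gram) ** 2.0
    if reduction == "mean":
        return resid.sum() * (1.0 / (a.shape[0] * a.shape[1]))
    if reduction == "sum":
        return resid.sum()
    raise ValueError(f"unknown recon_reduction {reduction!r}")


def decode(graph: BioGraph, h: Tensor, params: ModelParams) -> Tensor:
    """Decoded embeddings Z = Â H W_dec (one-layer graph convolution)."""
    if h.shape[0] != graph.m:
        raise ValueError(f"embedding rows {h.shape[0]} do not match m={graph.m}")
    a_hat = Tensor(graph.normalized_adjacency())
    return a_hat @ h @ params["dec_W"]


def reconstruction_loss(
    graph: BioGraph, h: Tensor, params: ModelParams, config: RunConfig
) -> Tensor:
    """L_d = ‖A − ZZᵀ‖²_F with Z decoded from the (gated) encoder output."""
    z = decode(graph, h, params)
    return gram_reconstruction_error(
        graph.adjacency, z, reduction=config.recon_reduction,
        link=config.decoder_link,
    )
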