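"""Independent loop-based oracles shared across test modules.

These deliberately avoid the package's vectorized implementations: Pearson
correlation via the direct covariance formula, attention via pair-by-pair
dense computation with an explicit admissibility predicate.
"""

import numpy as np


def pearson_oracle(block: np.ndarray) -> np.ndarray:
    """Direct covariance / std-product Pearson formula, looped."""
    n, na = block.shape
    out = np.eye(na)
    for i in range(na):
        for j in range(i + 1, na):
            xi = block[:, i] - block[:, i].mean()
            xj = block[:, j] - block[:, j].mean()
            out[i, j] = out[j, i] = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
    return out


def _ln(v, gamma, beta):
    return gamma * (v - v.mean()) / np.sqrt(v.var() + 1e-5) + beta


def dense_attention_oracle(x, block, grid, window, shifts):
    """One windowed transformer block computed pair-by-pair.

    Two tokens may attend iff, in rolled coordinates, they fall in the same
    window on every axis and on the same side of every cyclic wrap seam.
    """
    n, d = x.shape
    coords = np.array(np.unravel_index(np.arange(n), grid)).T
    rolled = (coords - np.array(shifts)) % np.array(grid)

    def may_attend(i, j):
        for ax in range(len(grid)):
            if rolled[i, ax] // window[ax] != rolled[j, ax] // window[ax]:
                return False
            s, g = shifts[ax], grid[ax]
            if s and (rolled[i, ax] >= g - s) != (rolled[j, ax] >= g - s):
                return False
        return True

    attn_in = np.stack([_ln(x[i], block.norm1.gamma.data, block.norm1.beta.data)
                        for i in range(n)])
    heads = block.attn.heads
    hd = d // heads
    q = attn_in @ block.attn.q.weight.data + block.attn.q.bias.data
    k = attn_in @ block.attn.k.weight.data + block.attn.k.bias.data
    v = attn_in @ block.attn.v.weight.data + block.attn.v.bias.data
    out = np.zeros((n, d))
    for h in range(heads):
        sl = slice(h * hd, (h + 1) * hd)
        for i in range(n):
            js = [j for j in range(n) if may_attend(i, j)]
            scores = np.array([q[i, sl] @ k[j, sl] for j in js]) / np.sqrt(hd)
            w = np.exp(scores - scores.max())
            w /= w.sum()
            out[i, sl] = sum(wj * v[j, sl] for wj, j in zip(w, js))
    out = out @ block.attn.proj.weight.data + block.attn.proj.bias.data
    x = x + out
    mlp_in = np.stack([_ln(x[i], block.norm2.gamma.data, block.norm2.beta.data)
                       for i in range(n)])
    hid = np.maximum(mlp_in @ block.mlp.fc1.weight.data + block.mlp.fc1.bias.data, 0)
    return x + hid @ block.mlp.fc2.weight.data + block.mlp.fc2.bias.data


def dense_encoder_oracle(tokens, enc):
    """Loop-based full-attention encoder: project + pos, blocks, GAP."""
    h = tokens @ enc.proj.weight.data + enc.proj.bias.data + enc.pos.data
    n, d = h.shape
    for blk in enc.blocks:
        heads, hd = blk.attn.heads, d // blk.attn.heads
        a_in = np.stack([_ln(h[i], blk.norm1.gamma.data, blk.norm1.beta.data)
                         for i in range(n)])
        q = a_in @ blk.attn.q.weight.data + blk.attn.q.bias.data
        k = a_in @ blk.attn.k.weight.data + blk.attn.k.bias.data
        v = a_in @ blk.attn.v.weight.data + blk.attn.v.bias.data
        attn_out = np.zeros((n, d))
        for hh in range(heads):
            sl = slice(hh * hd, (hh + 1) * hd)
            for i in range(n):
                scores = np.array([q[i, sl] @ k[j, sl] for j in range(n)])
                w = np.exp(scores / np.sqrt(hd))
                w /= w.sum()
                attn_out[i, sl] = w @ v[:, sl]
        h = h + attn_out @ blk.attn.proj.weight.data + blk.attn.proj.bias.data
        m_in = np.stack([_ln(h[i], blk.norm2.gamma.data, blk.norm2.beta.data)
                         for i in range(n)])
        hid = np.maximum(m_in @ blk.mlp.fc1.weight.data + blk.mlp.fc1.bias.data, 0)
        h = h + hid @ blk.mlp.fc2.weight.data + blk.mlp.fc2.bias.data
    return h.mean(axis=0)
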