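"""Numba kernels for the density-map network.

All tensors are channels-last (batch, height, width, channel) float32; 3x3
convolutions use zero padding and stride 1.  The backward pass reuses the
forward kernel with spatially flipped, channel-transposed weights.
"""

from numba import njit


@njit(fastmath=True, cache=True)
def conv3x3_fwd(x, W, b, y):
    """y[n,r,c,co] = b[co] + sum_{i,j,ci} x[n,r+i-1,c+j-1,ci] * W[i,j,ci,co]."""
    B, H, Wd, Ci = x.shape
    Co = W.shape[3]
    for n in range(B):
        for r in range(H):
            for c in range(Wd):
                for co in range(Co):
                    y[n, r, c, co] = b[co]
            for i in range(3):
                rr = r + i - 1
                if rr < 0 or rr >= H:
                    continue
                for j in range(3):
                    c0 = max(0, 1 - j)
                    c1 = Wd - max(0, j - 1)
                    for c in range(c0, c1):
                        cc = c + j - 1
                        for ci in range(Ci):
                            v = x[n, rr, cc, ci]
                            for co in range(Co):
                                y[n, r, c, co] += v * W[i, j, ci, co]


@njit(fastmath=True, cache=True)
def conv3x3_dw(x, dy, dW, db):
    """Weight/bias gradients: dW[i,j,ci,co] = sum x[n,r+i-1,c+j-1,ci]*dy[n,r,c,co]."""
    B, H, Wd, Ci = x.shape
    Co = dy.shape[3]
    dW[:] = 0.0
    db[:] = 0.0
    for n in range(B):
        for r in range(H):
            for c in range(Wd):
                for co in range(Co):
                    db[co] += dy[n, r, c, co]
            for i in range(3):
                rr = r + i - 1
                if rr < 0 or rr >= H:
                    continue
                for j in range(3):
                    c0 = max(0, 1 - j)
                    c1 = Wd - max(0, j - 1)
                    for c in range(c0, c1):
                        cc = c + j - 1
                        for ci in range(Ci):
                            v = x[n, rr, cc, ci]
                            for co in range(Co):
                                dW[i, j, ci, co] += v * dy[n, r, c, co]
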