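"""Optional numba acceleration.

Numerical cores are written in a numba-compatible subset of Python. When numba
is importable they are compiled in nopython mode; otherwise the same source
runs as plain Python (slower, identical semantics up to RNG streams).
"""

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap
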