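"""Minimal generator-based discrete-event kernel.

Events are ordered by (timestamp, sequence number): FIFO among simultaneous
events.  Processes are plain generators that yield either an integer delay
in milliseconds or a :class:`Signal` to wait on; ``Signal.fire(value)``
resumes all waiters with that value.
"""
from __future__ import annotations

import heapq
from typing import Callable, Optional


class Kernel:
    def __init__(self, start: int = 0) -> None:
        self.now: int = start
        self._heap: list[tuple[int, int, Callable]] = []
        self._seq = 0
        self._cancelled: set[int] = set()

    def schedule(self, delay: int, fn: Callable, *args) -> int:
        """Schedule ``fn(*args)`` after ``delay`` ms; returns a handle."""
        if delay < 0:
            raise ValueError("cannot schedule into the past")
        self._seq += 1
        heapq.heappush(self._heap,
                       (self.now + int(delay), self._seq, fn, args))
        return self._seq

    def cancel(self, handle: int) -> None:
        self._cancelled.add(handle)

    def run(self, until: Optional[int] = None) -> None:
        while self._heap:
            t, seq, fn, args = self._heap[0]
            if until is not None and t > until:
                break
            heapq.heappop(self._heap)
            if seq in self._cancelled:
                self._cancelled.discard(seq)
                continue
            self.now = t
            fn(*args)
        if until is not None:
            self.now = max(self.now, until)


class Signal:
    """One-to-many wakeup; waiters registered before fire() are resumed."""

    def __init__(self) -> None:
        self._waiters: list[Callable] = []

    def wait(self, cb: Callable) -> None:
        self._waiters.append(cb)

    def fire(self, value=None) -> None:
        waiters, self._waiters = self._waiters, []
        for cb in waiters:
            cb(value)


def spawn(kernel: Kernel, gen) -> None:
    """Run a generator as a process on the kernel."""

    def step(send_value=None):
        try:
            yielded = gen.send(send_value)
        except StopIteration:
            return
        if isinstance(yielded, Signal):
            yielded.wait(lambda v: step(v))
        else:
            kernel.schedule(int(yielded), step)

    step()
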