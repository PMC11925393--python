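"""A minimal process-oriented discrete event simulation kernel.

Processes are Python generators that yield commands to the simulation:

* ``Timeout(dt)``            — suspend for ``dt`` time units;
* ``Acquire(resource)``      — wait (FIFO) for one unit of a capacity-limited
                               resource; resumes once granted;
* ``Release(resource)``      — give the unit back, waking the first waiter.

The event calendar is a heap keyed by (time, insertion sequence), so
simultaneous events resolve in scheduling order and runs are reproducible for
a fixed seed.  Resource queues are strictly FIFO by request time, then by
request order.
"""

from __future__ import annotations

import heapq
import inspect
from collections import deque
from typing import Generator, Optional


class SimulationError(RuntimeError):
    """Raised when the simulation cannot make progress (deadlock)."""


class Timeout:
    __slots__ = ("delay",)

    def __init__(self, delay: float):
        if delay < 0:
            raise ValueError("timeout delay must be >= 0")
        self.delay = delay


class Acquire:
    __slots__ = ("resource",)

    def __init__(self, resource: "Resource"):
        self.resource = resource


class Release:
    __slots__ = ("resource",)

    def __init__(self, resource: "Resource"):
        self.resource = resource


Process = Generator[object, float, None]


class Resource:
    """A pool of identical servers with a FIFO wait queue."""

    __slots__ = ("name", "capacity", "in_use", "queue", "max_in_use")

    def __init__(self, name: str, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.name = name
        self.capacity = capacity
        self.in_use = 0
        self.queue: deque[Process] = deque()
        self.max_in_use = 0  # high-water mark, for conservation checks

    @property
    def available(self) -> int:
        return self.capacity - self.in_use

    def _seize(self) -> None:
        self.in_use += 1
        if self.in_use > self.capacity:  # pragma: no cover - invariant guard
            raise SimulationError(f"resource {self.name!r} over capacity")
        if self.in_use > self.max_in_use:
            self.max_in_use = self.in_use


class Simulation:
    """Event loop: schedule generator processes and run to exhaustion."""

    def __init__(self) -> None:
        self.now: float = 0.0
        self._heap: list[tuple[float, int, Process]] = []
        self._seq = 0

    def schedule(self, process: Process, at: float = 0.0) -> None:
        if at < self.now:
            raise ValueError("cannot schedule in the past")
        heapq.heappush(self._heap, (at, self._seq, process))
        self._seq += 1

    def _resume(self, process: Process) -> None:
        """Drive a process until it blocks (timeout or busy resource) or ends."""
        try:
            if inspect.getgeneratorstate(process) == inspect.GEN_CREATED:
                cmd = next(process)
            else:
                cmd = process.send(self.now)
        except StopIteration:
            return
        while True:
            if isinstance(cmd, Timeout):
                heapq.heappush(self._heap, (self.now + cmd.delay, self._seq, process))
                self._seq += 1
                return
            if isinstance(cmd, Acquire):
                res = cmd.resource
                if res.available > 0 and not res.queue:
                    res._seize()
                    try:
                        cmd = process.send(self.now)
                        continue
                    except StopIteration:
                        return
                res.queue.append(process)
                return
            if isinstance(cmd, Release):
                res = cmd.resource
                if res.in_use <= 0:
                    raise SimulationError(f"release of idle resource {res.name!r}")
                res.in_use -= 1
                if res.queue:
                    waiter = res.queue.popleft()
                    res._seize()
                    # wake the waiter at the current time, after this process blocks
                    heapq.heappush(self._heap, (self.now, self._seq, waiter))
                    self._seq += 1
                try:
                    cmd = process.send(self.now)
                    continue
                except StopIteration:
                    return
            raise SimulationError(f"unknown command {cmd!r}")

    def run(self) -> None:
        while self._heap:
            t, _, process = heapq.heappop(self._heap)
            self.now = t
            self._resume(process)

    def first_event_time(self) -> Optional[float]:
        return self._heap[0][0] if self._heap else None
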