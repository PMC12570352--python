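"""Dynamic-array containers used to track molecules, particles and reactions.

Reactions constantly create and destroy molecules, so the simulator needs
containers that support O(1) append, O(1) delete and stable external ids.
Two complementary variants are provided:

``DenseArray``
    A tightly packed array.  Deletion pops the last element into the hole
    ("pop and swap"), keeping the live region contiguous for fast
    vectorized iteration.  Because records move, every record carries an
    external id and a location map resolves ids to current slots.

``HoleyArray``
    An array with holes.  Slot ids are stable for the lifetime of a
    record; freed slots are chained through a free list and reused before
    the array grows.  A DenseArray of occupied slot ids makes iteration
    over live records cheap even when the array is sparse.

``ReactionList``
    The per-step bimolecular/unimolecular event list: a doubly linked list
    embedded into a HoleyArray chains all events of each educt so that
    consuming an educt invalidates exactly its events, while a DenseArray
    index supports unbiased uniform random selection of the next event to
    execute.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DenseArray", "HoleyArray", "ReactionList"]

_GROWTH = 2  # multiplicative capacity growth factor
_NONE = -1


class DenseArray:
    """Tightly packed dynamic array with pop-and-swap deletion.

    Records are arbitrary Python objects.  ``append`` issues monotonically
    increasing external ids (never reused within a run); ``index_of``
    resolves an id to the record's current slot in ``items[:len(self)]``.
    """

    def __init__(self, capacity: int = 4):
        self._items = [None] * max(1, capacity)
        self._ids = [None] * max(1, capacity)
        self._length = 0
        self._loc: dict[int, int] = {}
        self._next_id = 0

    def __len__(self) -> int:
        return self._length

    @property
    def capacity(self) -> int:
        return len(self._items)

    def append(self, item) -> int:
        """Append ``item``; returns its external id."""
        if self._length == len(self._items):
            grow = len(self._items) * (_GROWTH - 1)
            self._items.extend([None] * grow)
            self._ids.extend([None] * grow)
        idx = self._length
        ext_id = self._next_id
        self._next_id += 1
        self._items[idx] = item
        self._ids[idx] = ext_id
        self._loc[ext_id] = idx
        self._length += 1
        return ext_id

    def delete_index(self, index: int):
        """Delete the record at ``index``; returns the external id whose
        slot changed (None when the last element was deleted)."""
        if not 0 <= index < self._length:
            raise IndexError(f"index {index} out of range (length {self._length})")
        removed = self._ids[index]
        del self._loc[removed]
        last = self._length - 1
        moved = None
        if index != last:
            self._items[index] = self._items[last]
            moved = self._ids[last]
            self._ids[index] = moved
            self._loc[moved] = index
        self._items[last] = None
        self._ids[last] = None
        self._length = last
        return moved

    def delete_id(self, ext_id: int):
        return self.delete_index(self._loc[ext_id])

    def index_of(self, ext_id: int) -> int:
        return self._loc[ext_id]

    def get(self, ext_id: int):
        return self._items[self._loc[ext_id]]

    def __contains__(self, ext_id: int) -> bool:
        return ext_id in self._loc

    def __getitem__(self, index: int):
        if not 0 <= index < self._length:
            raise IndexError(index)
        return self._items[index]

    def ids(self) -> list[int]:
        return self._ids[: self._length]

    def items(self) -> list:
        return self._items[: self._length]


class HoleyArray:
    """Dynamic array with holes: stable slot ids, LIFO free-list reuse."""

    def __init__(self, capacity: int = 4):
        self._slots = [None] * max(1, capacity)
        self._is_hole = np.ones(max(1, capacity), dtype=bool)
        self._free_head = _NONE
        self._free_next = np.full(max(1, capacity), _NONE, dtype=np.int64)
        # seed the free list with all slots (LIFO: lowest index last pushed
        # first; push in reverse so slot 0 comes out first for readability)
        for i in range(len(self._slots) - 1, -1, -1):
            self._free_next[i] = self._free_head
            self._free_head = i
        self._occupied = DenseArray()
        self._occ_handle: dict[int, int] = {}  # slot -> occupied-index external id

    def __len__(self) -> int:
        return len(self._occupied)

    @property
    def capacity(self) -> int:
        return len(self._slots)

    def _grow(self):
        old = len(self._slots)
        new = old * _GROWTH
        self._slots.extend([None] * (new - old))
        self._is_hole = np.concatenate([self._is_hole, np.ones(new - old, dtype=bool)])
        self._free_next = np.concatenate(
            [self._free_next, np.full(new - old, _NONE, dtype=np.int64)]
        )
        for i in range(new - 1, old - 1, -1):
            self._free_next[i] = self._free_head
            self._free_head = i

    def insert(self, item) -> int:
        """Insert ``item`` into a free slot (reused before growing);
        returns the stable slot id."""
        if self._free_head == _NONE:
            self._grow()
        slot = self._free_head
        self._free_head = int(self._free_next[slot])
        self._free_next[slot] = _NONE
        self._slots[slot] = item
        self._is_hole[slot] = False
        self._occ_handle[slot] = self._occupied.append(slot)
        return slot

    def free(self, slot: int):
        """Free a live slot, pushing it on the free list."""
        if not 0 <= slot < len(self._slots) or self._is_hole[slot]:
            raise KeyError(f"slot {slot} is not a live slot")
        self._slots[slot] = None
        self._is_hole[slot] = True
        self._free_next[slot] = self._free_head
        self._free_head = slot
        self._occupied.delete_id(self._occ_handle.pop(slot))

    def __contains__(self, slot: int) -> bool:
        return 0 <= slot < len(self._slots) and not self._is_hole[slot]

    def __getitem__(self, slot: int):
        if slot not in self:
            raise KeyError(f"slot {slot} is not live")
        return self._slots[slot]

    def __setitem__(self, slot: int, item):
        if slot not in self:
            raise KeyError(f"slot {slot} is not live")
        self._slots[slot] = item

    def occupied_slots(self) -> list[int]:
        return self._occupied.items()


class _Event:
    __slots__ = ("payload", "educts", "nxt", "prv")

    def __init__(self, payload, educts):
        self.payload = payload
        self.educts = tuple(educts)  # up to 2 educt ids
        self.nxt = [_NONE, _NONE]  # per-educt next event slot
        self.prv = [_NONE, _NONE]  # per-educt previous event slot


class ReactionList:
    """Per-step reaction event list.

    Events carry up to two educt ids.  All events of one educt are chained
    through a doubly linked list embedded in the underlying HoleyArray
    (next/previous pointers per educt position, i.e. the 2x2 pointer
    block), with chain heads in a hash table.  A DenseArray of live event
    slots allows uniform random selection without bias.
    """

    def __init__(self):
        self._events = HoleyArray()
        self._heads: dict[object, int] = {}
        self._dense = DenseArray()
        self._dense_handle: dict[int, int] = {}

    def __len__(self) -> int:
        return len(self._events)

    def add(self, payload, educts) -> int:
        """Register an event for ``educts`` (1 or 2 ids); returns slot id."""
        ev = _Event(payload, educts)
        slot = self._events.insert(ev)
        for pos, educt in enumerate(ev.educts):
            head = self._heads.get(educt, _NONE)
            ev.nxt[pos] = head
            if head != _NONE:
                other = self._events[head]
                other.prv[other.educts.index(educt)] = slot
            self._heads[educt] = slot
        self._dense_handle[slot] = self._dense.append(slot)
        return slot

    def _unlink(self, slot: int):
        ev = self._events[slot]
        for pos, educt in enumerate(ev.educts):
            nxt, prv = ev.nxt[pos], ev.prv[pos]
            if prv == _NONE:
                if nxt == _NONE:
                    del self._heads[educt]
                else:
                    self._heads[educt] = nxt
            else:
                pev = self._events[prv]
                pev.nxt[pev.educts.index(educt)] = nxt
            if nxt != _NONE:
                nev = self._events[nxt]
                nev.prv[nev.educts.index(educt)] = prv
        self._events.free(slot)
        self._dense.delete_id(self._dense_handle.pop(slot))

    def remove(self, slot: int):
        self._unlink(slot)

    def clear_for_educt(self, educt):
        """Remove every event that contains ``educt``; other educts'
        chains stay intact."""
        while educt in self._heads:
            self._unlink(self._heads[educt])

    def payload(self, slot: int):
        return self._events[slot].payload

    def educts_of(self, slot: int):
        return self._events[slot].educts

    def pick_random(self, rng: np.random.Generator) -> int:
        """Uniformly random live event slot."""
        n = len(self._dense)
        if n == 0:
            raise IndexError("reaction list is empty")
        return self._dense[int(rng.integers(n))]

    def pop_random(self, rng: np.random.Generator):
        """Pick a uniformly random event, remove it, return (payload, educts)."""
        slot = self.pick_random(rng)
        ev = self._events[slot]
        payload, educts = ev.payload, ev.educts
        self._unlink(slot)
        return payload, educts

    def live_slots(self) -> list[int]:
        return list(self._dense.items())
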