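"""Atlas mapping of ICNs to subdomains and functional domains."""

from __future__ import annotations

from dataclasses import dataclass

#: The seven functional domains: cerebellar, visual, paralimbic,
#: subcortical, sensorimotor, higher cognition, triple network.
DOMAINS = ("CB", "VI", "PL", "SC", "SM", "HC", "TN")


@dataclass(frozen=True)
class AtlasMap:
    """Maps each 1-based ICN id to a subdomain and each subdomain to a
    domain. Every ICN belongs to exactly one subdomain, every subdomain to
    exactly one domain."""

    icn_to_subdomain: dict[int, str]
    subdomain_to_domain: dict[str, str]

    def __post_init__(self) -> None:
        missing = {sd for sd in self.icn_to_subdomain.values()
                   if sd not in self.subdomain_to_domain}
        if missing:
            raise ValueError(f"subdomain(s) without a domain: {sorted(missing)}")

    @property
    def n_icn(self) -> int:
        return len(self.icn_to_subdomain)

    @property
    def domains(self) -> tuple[str, ...]:
        seen: list[str] = []
        for d in self.subdomain_to_domain.values():
            if d not in seen:
                seen.append(d)
        return tuple(seen)

    @property
    def subdomains(self) -> tuple[str, ...]:
        return tuple(self.subdomain_to_domain)

    def domain_of(self, icn_id: int) -> str:
        try:
            return self.subdomain_to_domain[self.icn_to_subdomain[icn_id]]
        except KeyError:
            raise KeyError(f"ICN id {icn_id} missing from atlas") from None

    def icns_in_domain(self, domain: str) -> tuple[int, ...]:
        return tuple(i for i in sorted(self.icn_to_subdomain)
                     if self.domain_of(i) == domain)

    def icns_in_subdomain(self, subdomain: str) -> tuple[int, ...]:
        return tuple(i for i, sd in sorted(self.icn_to_subdomain.items())
                     if sd == subdomain)


# Synthetic stand-in for the 105-ICN atlas layout: the true ICN->subdomain
# assignment is not published as a table, so contiguous index ranges
# consistent with the published counts (105 ICNs, 14 subdomains, 7 domains)
# and with the ICN numbering used in the study's result tables are used.
_DEFAULT_LAYOUT: tuple[tuple[str, str, int, int], ...] = (
    # (subdomain, domain, first icn, last icn) inclusive, 1-based
    ("CB-CB", "CB", 1, 13),
    ("VI-OT", "VI", 14, 18),
    ("VI-OC", "VI", 19, 25),
    ("PL-PL", "PL", 26, 36),
    ("SC-EH", "SC", 37, 39),
    ("SC-ET", "SC", 40, 45),
    ("SC-BG", "SC", 46, 54),
    ("SM-SM", "SM", 55, 68),
    ("HC-IT", "HC", 69, 75),
    ("HC-TP", "HC", 76, 80),
    ("HC-FR", "HC", 81, 89),
    ("TN-CE", "TN", 90, 93),
    ("TN-DM", "TN", 94, 101),
    ("TN-SA", "TN", 102, 105),
)


def default_atlas() -> AtlasMap:
    """The bundled 105-ICN / 14-subdomain / 7-domain atlas (synthetic
    stand-in layout; see module comment)."""
    icn_to_sub: dict[int, str] = {}
    sub_to_dom: dict[str, str] = {}
    for sub, dom, lo, hi in _DEFAULT_LAYOUT:
        sub_to_dom[sub] = dom
        for icn in range(lo, hi + 1):
            icn_to_sub[icn] = sub
    return AtlasMap(icn_to_subdomain=icn_to_sub, subdomain_to_domain=sub_to_dom)
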