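OX	synthetic stand-in for KEGG 00190 oxidative phosphorylation (mouse-style symbols, 116 members)	Ndufa1	Ndufa2	Ndufa3	Ndufa4	Ndufa5	Ndufa6	Ndufa7	Ndufa8	Ndufa9	Ndufa10	Ndufa11	Ndufa12	Ndufa13	Ndufab1	Ndufb2	Ndufb3	Ndufb4	Ndufb5	Ndufb6	Ndufb7	Ndufb8	Ndufb9	Ndufb10	Ndufb11	Ndufc1	Ndufc2	Ndufs1	Ndufs2	Ndufs3	Ndufs4	Ndufs5	Ndufs6	Ndufs7	Ndufs8	Ndufv1	Ndufv2	Ndufv3	Sdha	Sdhb	Sdhc	Sdhd	Uqcrb	Uqcrc1	Uqcrc2	Uqcrfs1	Uqcrh	Uqcrq	Uqcr10	Uqcr11	Cyc1	mt-Cytb	Cox4i1	Cox4i2	Cox5a	Cox5b	Cox6a1	Cox6a2	Cox6b1	Cox6b2	Cox6c	Cox7a1	Cox7a2	Cox7a2l	Cox7b	Cox7c	Cox8a	Cox8b	Cox10	Cox11	Cox15	Cox17	mt-Co1	mt-Co2	mt-Co3	Atp5a1	Atp5b	Atp5c1	Atp5d	Atp5e	Atp5f1	Atp5g1	Atp5g2	Atp5g3	Atp5h	Atp5j	Atp5j2	Atp5k	Atp5l	Atp5o	mt-Atp6	mt-Atp8	Ppa1	Ppa2	Lhpp	Atp4a	Atp4b	Atp12a	Atp6v0a1	Atp6v0a2	Atp6v0b	Atp6v0c	Atp6v0d1	Atp6v0d2	Atp6v0e	Atp6v1a	Atp6v1b1	Atp6v1b2	Atp6v1c1	Atp6v1d	Atp6v1e1	Atp6v1f	Atp6v1g1	Atp6v1g2	Atp6v1h	Atp6ap1	Tcirg1
glycolysis	synthetic stand-in for KEGG 00010 glycolysis/gluconeogenesis (mouse-style symbols, 60 members)	Hk1	Hk2	Hk3	Gck	Gpi1	Pfkl	Pfkm	Pfkp	Aldoa	Aldob	Aldoc	Tpi1	Gapdh	Gapdhs	Pgk1	Pgk2	Pgam1	Pgam2	Eno1	Eno2	Eno3	Pkm	Pklr	Ldha	Ldhb	Ldhc	Ldhal6b	Adh1	Adh5	Adh7	Akr1a1	Aldh2	Aldh1b1	Aldh3a1	Aldh3a2	Aldh3b1	Aldh7a1	Aldh9a1	Acss1	Acss2	Galm	Pgm1	Pgm2	Bpgm	Minpp1	Fbp1	Fbp2	Pdha1	Pdha2	Pdhb	Dlat	Dld	Pck1	Pck2	G6pc	G6pc2	G6pc3	Adpgk	Hkdc1	Eno1b
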