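>ELT1_N synthetic 55-column class template (amino DBD of two-finger factors; TPLWRR)
CVNCGATATPLWRRDGTGNYLCNACGLYNKLNGINRPLIRPQKRLSVQDRRNTKK
>ELT1_C synthetic 55-column class template (carboxyl DBD of two-finger factors; TTLWRR)
CANCQTSTTTLWRRNANGEPVCNACGLYFKLHNVNRPKTMRKEGIQTRNRKVTSK
>ELT2 synthetic 55-column class template (DBD downstream of the degenerate finger; TTLWRR)
CTNCKASTTTLWRRSAEGGHVCNACGLYYKLHGVPRPLAMKKDGIQTRKRKPKNS
>ELT3 synthetic 55-column class template (divergent single-finger class; TSLWRR)
CRECNGATSLWRREGLPVTMFCSMCSKTRGRFAQKVEHMMNTGEVKPKQITVKAR
>ELT5 synthetic 55-column class template (well-conserved single-finger class; TTAWRR)
CSNCGASTTAWRRTPQGAMVLCNACGLFFKMHNEHRPIESRRNAIRTRKRKPVSD
>ELTX synthetic 55-column divergent template (catch-all class; no diagnostic hexapeptide)
CDGCMNPEFKGHTAVQIDYNLCTSCKDLHGRMKAVENPTFIRGDKAQMYVHNRTE
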