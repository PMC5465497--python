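>IgG1-CH3 human IGHG1 CH3 (germline), IMGT C-DOMAIN layout
EPQVYTLPPSRDELTKNQVSLTCLVKGFYPSDIAVEWESNGQPENNYKTTPPVLDSDGSFFLYSKLTVDKSRWQQGNVFSCSVMHEALHNHYTQKSLSLSPGK
>IgG3-CH3 human IGHG3 CH3, curated: IgG1 CH3 with the Protein A region differences (115 R, 116 F)
EPQVYTLPPSRDELTKNQVSLTCLVKGFYPSDIAVEWESNGQPENNYKTTPPVLDSDGSFFLYSKLTVDKSRWQQGNVFSCSVMHEALHNRFTQKSLSLSPGK
>TCR-Ca human TRAC constant domain, curated reconstruction
IQQPYPLVYQLRDSKKSSDKSVCLFTGFDSQTNVSVWASNKSDFAANYFTNSVIDPEDTFSFVPWSNKSDFAMETDTNLNCDVKLVEKSFETDTNLNFQNLSV
>TCR-Cb human TRBC constant domain, curated reconstruction
EDENAVFPPEVAVFEISHQTLVCLATGFFPDHVELSWWVNGKEVHNDKRDALLSESRYSACLSSRLRVSATFWQNPRNHFCQVQFYGLSENDEWTQDRAKPVT
>TCR-Cg human TRGC constant domain, curated reconstruction
DKELTDLVSPKPTIFLPSKSAICLQSGKFFPDVIKIWHEEKSNTIGSFQNETAMETNDTYSMTFWLSVPEKSLDKEHRIVCRHENNKNGVDQEIIFPPIKTDV
>TCR-Cd human TRDC constant domain, curated reconstruction
SQQPSTFVFVMKNGTNVSQTAVCLVEGEFYPKDIRIWLVSSKKITEFKDSAVISDPSGKYANVLFGKYEDSNSVTQSVHDCNKTVHSTDFEVKTDSTDHVKPK
>IgA-CH3 human IGHA1 CH3, curated reconstruction
RPEVHLLPPPSEELANELVTLTCLARGFSPKDVLVRWLQGSLPREKYLTWASRQEPSQGTTVTSILRVAAEDWKKGDTFSCMVGHEALPLAFTQKTIDRLAGK
>IgD-CH3 human IGHD CH3, curated reconstruction
VQDPFSVFVFPPSEDISKEALVCLIQGDFSPADIFIWQSRGEPIQETRFSPTLNESGSNTLTFPRVQVTAEDWKNGETFSCVVGHEALHNHLTQTISRSLEVS
>IgM-CH4 human IGHM CH4, curated reconstruction
VFAIPPSFASIFLTKSTKLTATCLVTGDLTTYDSVTWISTRQNGEAVKTHTNISESHPNATFSAVGEASILEDDWNSGERCFTTHTDLPSRVKQTISRPKGVA
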