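table,drug,unit,cell_line,parameter,increment,value,censored
3,MLN4924,nM,VCaP,Area,1,18,none
3,MLN4924,nM,VCaP,CE,1,20,none
3,MLN4924,nM,VCaP,CE,2,600,above_max
3,MLN4924,nM,VCaP,CE_2D,1,500,none
3,MLN4924,nM,VCaP,LysoT,1,20,none
3,MLN4924,nM,VCaP,LysoT,2,500,none
3,MLN4924,nM,VCaP,ATP,1,20,none
3,MLN4924,nM,VCaP,ATP,2,600,above_max
3,MLN4924,nM,VCaP,ATP_2D,1,500,none
3,MLN4924,nM,VCaP,WB,1,8,none
3,MLN4924,nM,LNCaP,Area,1,18,none
3,MLN4924,nM,LNCaP,Area,2,190,none
3,MLN4924,nM,LNCaP,P2A,1,250,none
3,MLN4924,nM,LNCaP,CE,1,180,none
3,MLN4924,nM,LNCaP,CE_2D,1,130,none
3,MLN4924,nM,LNCaP,LysoT,1,70,none
3,MLN4924,nM,LNCaP,ATP,1,70,none
3,MLN4924,nM,LNCaP,ATP_2D,1,50,none
3,MLN4924,nM,LNCaP,WB,1,10,none
4,Cisplatin,uM,VCaP,Area,1,5,none
4,Cisplatin,uM,VCaP,P2A,1,50,none
4,Cisplatin,uM,VCaP,CE,1,5,none
4,Cisplatin,uM,VCaP,CE,2,25,none
4,Cisplatin,uM,VCaP,LysoT,1,50,none
4,Cisplatin,uM,VCaP,ATP,1,4,none
4,Cisplatin,uM,VCaP,ATP,2,60,none
4,Cisplatin,uM,VCaP,ATP_2D,1,40,none
4,Cisplatin,uM,LNCaP,Area,1,4,none
4,Cisplatin,uM,LNCaP,P2A,1,30,none
4,Cisplatin,uM,LNCaP,CE,1,4,none
4,Cisplatin,uM,LNCaP,CE,2,30,none
4,Cisplatin,uM,LNCaP,LysoT,1,30,none
4,Cisplatin,uM,LNCaP,ATP,1,30,none
4,Cisplatin,uM,LNCaP,ATP_2D,1,30,none
4,Docetaxel,nM,VCaP,Area,1,5,none
4,Docetaxel,nM,VCaP,P2A,1,1.5,none
4,Docetaxel,nM,VCaP,CE,1,5,none
4,Docetaxel,nM,VCaP,LysoT,1,5,none
4,Docetaxel,nM,VCaP,ATP,1,3,none
4,Docetaxel,nM,VCaP,ATP_2D,1,2,none
4,Docetaxel,nM,LNCaP,Area,1,10,none
4,Docetaxel,nM,LNCaP,P2A,1,2,none
4,Docetaxel,nM,LNCaP,CE,1,15,none
4,Docetaxel,nM,LNCaP,LysoT,1,15,none
4,Docetaxel,nM,LNCaP,ATP,1,15,none
4,Docetaxel,nM,LNCaP,ATP_2D,1,2,none
4,Etoposide,uM,VCaP,Area,1,0.8,none
4,Etoposide,uM,VCaP,P2A,1,5,none
4,Etoposide,uM,VCaP,CE,1,0.3,none
4,Etoposide,uM,VCaP,CE,2,4,none
4,Etoposide,uM,VCaP,LysoT,1,1,none
4,Etoposide,uM,VCaP,ATP,1,1,none
4,Etoposide,uM,VCaP,ATP_2D,1,1,none
4,Etoposide,uM,LNCaP,Area,1,1,none
4,Etoposide,uM,LNCaP,CE,1,0.8,none
4,Etoposide,uM,LNCaP,LysoT,1,1.5,none
4,Etoposide,uM,LNCaP,ATP,1,2,none
4,Etoposide,uM,LNCaP,ATP_2D,1,2,none
4,ARN-509,nM,VCaP,Area,1,80,none
4,ARN-509,nM,VCaP,CE,1,400,none
4,ARN-509,nM,VCaP,LysoT,1,100,none
4,ARN-509,nM,VCaP,ATP,1,100,none
4,ARN-509,nM,VCaP,ATP_2D,1,150,none
4,ARN-509,nM,LNCaP,Area,1,13,none
4,ARN-509,nM,LNCaP,CE,1,15,none
4,ARN-509,nM,LNCaP,LysoT,1,13,none
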