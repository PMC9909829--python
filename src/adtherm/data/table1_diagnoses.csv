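true_class,tumor_type,cytology,histopathology
benign,Adenoma,1,3
benign,Benign epithelial/adnexal cyst/tumor,4,1
benign,Benign melanoma,0,1
benign,Lipoma,20,1
benign,Papilloma,1,0
benign,Perineal adenoma,1,1
benign,Plasmacytoma,0,1
benign,Reactive lymph node,2,0
benign,Sebaceous adenoma,3,0
benign,Sebaceous hamartoma,0,1
benign,Sebaceous hyperplasia,1,0
malignant,Adenocarcinoma,0,3
malignant,Cutaneous hemangiosarcoma,0,3
malignant,Lymphoma,10,0
malignant,Mast cell tumor,3,2
malignant,Metastatic lymph node (hemangiosarcoma),1,0
malignant,Metastatic lymph node (melanoma),0,1
malignant,Osteosarcoma,0,1
malignant,Soft tissue sarcoma,0,1
malignant,Undifferentiated neoplasia,0,2
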